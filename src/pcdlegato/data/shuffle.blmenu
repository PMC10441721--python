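# Reference menu: window-shuffle of the selected sequences.
name "Shuffle"
icon "$BIRCH/public_html/images/xylem.png"
tip "Randomize residues locally, within a sliding window"
var "window"
    type number
    label "Window size"
    min 1
    default 10
    max 100
var "in1"
    type tempfile
    direction in
    format fasta
var "out1"
    type tempfile
    direction out
    format fasta
var "bloutput"
    type chooser
    label "Output to new window?"
    default "Yes"
    choices
        "Yes" "-o %out1% %NEWINSTANCE%"
        "No" "-o %out1%"
panel
    "window"
    "bloutput"
    shell "shuffle.py %in1% -w %WINDOW% %BLOUTPUT%"
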