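"""Helper computations: read-pair guessing and Entrez query building.

Pairs forward/reverse sequencing-read files by their R1/R2 name tokens,
renders the pairing in two assembler dialects, and assembles a boolean
Entrez search expression — all pure string computation, no network.
"""

from pcdlegato import (QueryClause, build_entrez_expression, guess_pairs,
                       pair_fragment)

files = ["s1-R1.fq", "s1-R2.fq", "s2-R1.fq", "notes.txt"]
table = guess_pairs(files)
print("input files:", files)
for fwd, rev in table.rows:
    print(f"  pair: {fwd}  <->  {rev or '(single-end)'}")
# notes.txt is excluded (not a fastq extension); s2-R1.fq has no mate.

pair = guess_pairs(["seqs-R1.fq", "seqs-R2.fq"])
print("spades flags: ", pair_fragment(pair, "cli_flags"))
print("soap config:  ", pair_fragment(pair, "config_lines").replace("\n", " / "))

clause = QueryClause(terms=(("ORGN", "algae"), ("FKEY", "mobile_element")),
                     operators=("AND",))
expr = build_entrez_expression(clause, molecule="genomic",
                               length_range=(1, 500000))
print("entrez query: ", expr)
# The bracketed tags are Entrez search fields: organism, feature key,
# molecule property, and sequence-length range.
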