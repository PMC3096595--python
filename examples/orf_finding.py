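"""Six-frame ORF finding and one-CDS-per-contig selection.

Contigs are translated in all six frames; the coding sequence per contig is
the ORF with the best database hit when one exists, otherwise the longest
peptide (the rule used to pick coral CDSs from transcriptome contigs).
"""

from netfootprint import BestHit, BestHitTable, find_orfs, select_cds

contig = ("ATGAAATTTGGGCCCATTTAAGGGTTT"           # frame +1 ORF then a stop
          "TTACATTTTCATTTTCATTTTCAT")             # reverse-strand ORF
orfs = find_orfs("c1", contig, min_aa_length=3)
print(f"{len(orfs)} ORFs of >= 3 aa in contig c1:")
for o in orfs:
    print(f"  frame {o.frame:+d}  {o.start}-{o.end}  {o.peptide}")

# no database hit -> the longest ORF is chosen
chosen = select_cds({"c1": orfs}, BestHitTable())
orf, tag = chosen["c1"]
print(f"\nno hit: chose {orf.peptide} ({tag})")

# a hit on a shorter ORF overrides length
short = min(orfs, key=lambda o: len(o.peptide))
hits = BestHitTable([BestHit("c1", short.orf_id, True,
                             bitscore=250.0, evalue=1e-40)])
orf, tag = select_cds({"c1": orfs}, hits)["c1"]
print(f"with hit: chose {orf.peptide} ({tag})")
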