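"""Screen genomes and viral proteomes by assembly quality.

Cellular genomes must miss at most 4 of the 40 universal single-copy marker
genes, assemble to fewer than 300 contigs, and reach an N50 of at least
10 kb; viral proteomes must retain at least 3 proteins after polyprotein
cleaving.
"""
from ogforge import GenomeRecord, assess_genome, assess_viral_proteome, compute_n50

markers = [f"m{i:02d}" for i in range(40)]

good = GenomeRecord("ecoli_draft", (300_000, 150_000, 80_000),
                    frozenset(markers[:38]), n_proteins=4200)
shredded = GenomeRecord("meta_bin_7", (9_000,) * 350,
                        frozenset(markers), n_proteins=2900)
phage = GenomeRecord("phage_X", (), frozenset(), n_proteins=2, is_viral=True)

for rec in (good, shredded):
    res = assess_genome(rec)
    n50 = compute_n50(rec.contig_lengths)
    print(f"{res.genome_id:12s} N50={n50:>7d} passed={res.passed} "
          f"reasons={list(res.failure_reasons)}")
res = assess_viral_proteome(phage)
print(f"{res.genome_id:12s} {'':14s}passed={res.passed} "
      f"reasons={list(res.failure_reasons)}")

# The draft passes every rule; the metagenomic bin fails on contig count
# and N50 despite complete markers; the 2-protein phage is too small.
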