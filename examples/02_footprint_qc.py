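"""Run the footprint QC battery on simulated positional reads.

Generates ~30 nt ribosome footprints with a 13 nt P-site offset and
triplet periodicity, then recovers those properties from the reads
alone — the same checks one runs on real ribo-seq libraries before
trusting downstream counts.
"""

from ribote import SimConfig, filter_by_length, make_transcriptome, qc_report, simulate_reads

config = SimConfig(n_genes=300, seed=21)
transcriptome = make_transcriptome(config)
reads = simulate_reads(config, transcriptome, assay="rpf", n_reads=100_000)

# the standard retention window for ribosome footprints
reads = filter_by_length(reads, 27, 32)
report = qc_report(reads, transcriptome)

print(f"reads after 27-32 nt filter: {len(reads):,}")
print("length histogram (top 3):")
print(report.length_hist.sort_values(ascending=False).head(3).to_string())

f0, f1, f2 = report.frame_fractions
print(f"\nframe fractions: {f0:.3f} / {f1:.3f} / {f2:.3f} "
      f"(chi2 = {report.frame_chi2:,.0f}, p = {report.frame_pvalue:.2e})")
print("a tiny p-value = strong triplet periodicity, the signature of "
      "codon-wise ribosome movement; RNA-seq reads would show p ~ uniform")

print(f"\nP-site offsets by length: {report.offsets_by_length}")
print("13 nt is the distance from a footprint's 5' end to the ribosomal "
      "P site; reads are shifted by it before CDS counting")

print(f"\nregion fractions: { {k: round(v, 3) for k, v in report.region_fractions.items()} }")
print("footprints come from translating ribosomes, so nearly all P-sites "
      "fall inside coding sequence")
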