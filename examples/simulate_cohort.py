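"""Generate a small synthetic study and inspect its planted truth.

The generator emulates the real design: two groups of 9 two-color
methylation-sensitive restriction arrays, a genome annotation, and coupled
expression matrices (4v4 and 5v5).  Here we shrink the genome and probe count
so the script runs in a couple of seconds.
"""

from methlink import SyntheticConfig, generate_annotation, generate_expression, \
    generate_methylation_arrays

config = SyntheticConfig(
    n_probes=4_000, n_transcripts=300, chrom_length=10_000_000,
    n_cpg_islands=200, planted_unmeth_normal_only=200,
    planted_unmeth_asthma_only=200, planted_unmeth_both=800,
    planted_dual_count=10, planted_de_count=80, master_seed=42,
)
annotation = generate_annotation(config)
arrays, truth = generate_methylation_arrays(config, annotation)
expr, truth = generate_expression(config, annotation, truth)

exp_probes = truth.probes[~truth.probes["is_control"]]
print(f"transcripts: {len(annotation.transcripts)}, "
      f"CpG islands: {len(annotation.cpg_islands)}")
print(f"arrays: {len(arrays)} ({arrays[0].array_id} .. {arrays[-1].array_id})")
print(f"experimental probes: {len(exp_probes)}, "
      f"controls: {int(truth.probes['is_control'].sum())}")
print("planted unmethylated probes per truth state:")
print(exp_probes.groupby(["state_normal", "state_asthma"]).size().to_string())
de = truth.transcripts["de_state"].value_counts()
print(f"planted DE transcripts: up={de.get('up', 0)} down={de.get('down', 0)}")
# The per-probe states above are what the methylation stage must recover;
# the DE states are what the expression stage must recover.
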