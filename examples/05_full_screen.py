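"""Run the complete in-silico screen end to end and emit all reports.

Simulates a small library plus one genome per expected family
representative, then runs clustering, representative selection, promoter
discovery/verification, triage against a reference enzyme, and the
diversity tree in one call.  Reports land in ./screen_output/.
"""

from rnapscreen import cluster, synthetic
from rnapscreen.pipeline import emit_reports, run_screen
from rnapscreen.triage import ScreenConfig

MOTIF = "TAATACGACTCACTATAGGG"

records, _ = synthetic.generate_rnap_library(
    n_families=3, sizes=[4, 3, 2], within_div=0.04, between_div=0.45,
    rng_seed=42, seq_length=120,
)
records[0].characterized = True  # stands in for the known reference enzyme

# pre-compute the expected representatives so each gets a genome
matrix = cluster.build_identity_matrix(records)
s2 = cluster.cluster_stage2(cluster.cluster_stage1(matrix), records, matrix=matrix)
genomes = {}
for fam, rep in s2.representative.items():
    genome, _ = synthetic.generate_phage_genome_with_promoters(
        20000, 0.5, 12, MOTIF, copies=4, max_mismatches=1, rng_seed=100 + fam,
        genome_id=f"genome_{rep}",
    )
    genomes[rep] = genome

config = ScreenConfig(
    reference_id=records[0].accession,
    reference_domain_interval=(40, 100),
)
result = run_screen(records, genomes, config)
files = emit_reports(result, "screen_output")

print(f"families          : {len(result.stage2)}")
print(f"promoter statuses : {dict(sorted(result.promoter_status.items()))}")
print(f"triage counts     : {result.triage.counts}")
print("reports written   :", ", ".join(p.name for p in files))
# Every family representative with a genome should end 'predicted'; the
# triage counts classify all nine enzymes, and re-running this script
# reproduces every output file byte for byte.
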