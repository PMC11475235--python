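"""Partition the theoretical RNAP biocatalyst solution space.

Loads the packaged 351-enzyme manifest (class structure mirrors the
published screen; identity values are synthetic placeholders) and applies
the two in-silico filters: DNA-binding-domain identity to T7 below 30%
predicts an unusable promoter, and overall identity above 75% to an already
characterized enzyme predicts a redundant bioproduction phenotype.
"""

from rnapscreen import seqio, triage

manifest = seqio.load_solution_space()
report = triage.partition_solution_space(manifest)

print(f"total enzymes               : {report.total}")
print(f"excluded (binding < 30%)    : {report.counts['excluded_low_binding']}")
print(f"remaining after that filter : {report.remaining_after_binding_filter}")
print(f"redundant (overall > 75%)   : {report.counts['redundant_high_identity']}")
print(f"validated in this screen    : {report.counts['validated_novel']}")
print(f"candidate total             : {report.candidate_total}")
print(f"additional future targets   : {report.additional_targets}")
# candidate_total counts enzymes predicted to be both active and
# phenotypically novel; subtracting the already-validated ones leaves the
# promising targets still untested.
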