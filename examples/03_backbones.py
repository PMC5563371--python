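"""NRPS module segmentation and consensus backbone prediction.

Builds an NRPS cluster family whose adenylation domains carry three
predictor calls each (one engineered tie), segments the domain list
into modules, and predicts the peptide backbone by majority vote.
"""

from bgcnet import (
    FamilySpec,
    build_architecture,
    consensus_backbone,
    generate_cluster_family,
    load_signature_table,
    segment_modules,
)

mods = segment_modules(["Condensation", "AMP-binding", "PCP",
                        "KS", "AT", "ACP", "KR", "DH",
                        "KS", "KR"])
print("segmentation:", [(m.kind, m.domains) for m in mods])
# The first module is a complete NRPS (C-A-PCP), the second a complete
# PKS with KR/DH tailoring, and the trailing KS-KR lacks AT/ACP so it
# stays 'incomplete'.

spec = FamilySpec(name="demo", n_members=2, n_predictors_agreeing=3,
                  substrates=("gly", "x", "pro"),
                  domain_template=("Condensation", "AMP-binding", "PCP",
                                   "Condensation", "AMP-binding", "PCP",
                                   "Condensation", "AMP-binding", "PCP", "TE"))
table = load_signature_table()
for rec in generate_cluster_family(spec, seed=11):
    arch = build_architecture(rec)
    print(f"{rec.cluster_id}: {len(arch.modules)} modules, "
          f"backbone {consensus_backbone(rec, table)}")
# 'x' marks the engineered position where the three predictors disagree
# three ways, so no strict majority exists.
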