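"""Validate SC pairs in a synthetic patient cohort with Firth-penalized Cox.

The generator plants a protective hazard ratio of 0.4 per disrupted partner
(SYNE2/SON), active ONLY in TP53-mutant patients. The validation fits the
partner-disruption burden separately in the two TP53 strata: a real SC
survival effect shows up in the mutant stratum and vanishes in wild-type.
"""

import numpy as np
import pandas as pd

from scinfer import (
    PatientCohortConfig,
    build_disruption_matrix,
    fit_firth_cox,
    kaplan_meier,
    partner_burden,
    read_maf,
    simulate_patient_cohort,
)

cohort = simulate_patient_cohort(PatientCohortConfig(n_patients=800, seed=2))
cohort.write("patients")  # cohort.maf + clinical.tsv + truth.json

variants = read_maf("patients/cohort.maf")
patients = list(cohort.clinical["patient_id"])
matrix = build_disruption_matrix(variants, None, patients, ["TP53", "SYNE2", "SON"])

pb = partner_burden(matrix, "TP53", ["SYNE2", "SON"])
clinical = cohort.clinical.drop(columns=["anchor_mutant"]).set_index("patient_id")
design = pb.join(clinical, how="inner")
design = design.rename(columns={"os_time": "time", "os_event": "event"})

for stratum, flag in (("TP53-mutant", True), ("TP53-wild-type", False)):
    sub = design.loc[design["anchor_mutant"] == flag]
    fit = fit_firth_cox(sub, ["burden"])
    print(
        f"{stratum}: n={fit.n}, events={fit.n_events}, "
        f"HR per disrupted partner = {fit.hazard_ratio[0]:.3f} "
        f"(beta {fit.beta[0]:+.3f}), penalized-LRT p = {fit.p_value[0]:.3g}"
    )

mutant = design.loc[design["anchor_mutant"]].copy()
mutant["burden_group"] = mutant["burden"].map({0: "0 partners", 1: "1 partner", 2: "2 partners"})
curves = kaplan_meier(mutant, group_col="burden_group", risk_times=[0, 500, 1000])
for label, c in curves.items():
    print(f"KM {label}: S(500) = {c.survival_at(500):.2f}, at risk @500 = {c.risk_table[500]}")
# Inside the TP53-mutant stratum HR < 1 with small p: each disrupted partner
# improves survival, as planted. In wild-type patients the HR is ~1.
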