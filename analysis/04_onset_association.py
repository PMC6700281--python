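"""Residual-onset phenotyping and modifier association on the cohort.

Computes residual age at onset from the assay-estimated CAG, restricts to
the 40-55 CAG window, dichotomizes at 30%, and runs the fixed-effect
association of each modifier SNP with the residual phenotype (sex as a
covariate).  Then demonstrates the mis-estimated-CAG artifact: the SNP
tagging CAA-loss chromosomes shows an artificial hastening signal that
disappears once residuals are recomputed from the true CAG length.

Writes results/association.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from httrepeat import modifier_stats as ms
from httrepeat import onset_phenotype as op

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "sim" / "cohort.tsv", sep="\t")
    dosages = pd.read_csv(RESULTS / "sim" / "dosages.tsv", sep="\t",
                          index_col="id")
    model = op.default_model()
    a, b = model.coef
    print(f"onset model: ln(AO) = {a:.3f} {b:+.4f} * CAG "
          f"(AO(42) = {model.expected(42):.1f} y)")

    cohort = op.filter_cohort(cohort)
    df = op.add_residuals(cohort, model)
    late, early = op.dichotomize(df, 0.30)
    print(f"{len(df)} subjects in the 40-55 CAG window; "
          f"dichotomized groups: late {len(late)}, early {len(early)}")

    dosages = dosages.loc[df["id"]]
    sex = (df["sex"] == "M").to_numpy(dtype=float).reshape(-1, 1)
    y = df["residual"].to_numpy()
    y_true = op.add_residuals(df, model, use_true=True)["residual"].to_numpy()

    rows = []
    for snp in dosages.columns:
        d = dosages[snp].to_numpy(dtype=float)
        res = ms.marginal_association(d, y, covariates=sex)
        res_true = ms.marginal_association(d, y_true, covariates=sex)
        rows.append({
            "snp": snp,
            "maf": d.sum() / (2 * len(d)),
            "beta_years": round(res.beta, 2),
            "p": res.p,
            "beta_true_cag": round(res_true.beta, 2),
            "p_true_cag": res_true.p,
        })
        print(f"{snp:>14}: beta {res.beta:+5.2f} y/allele (p = {res.p:.2g})"
              f" | true-CAG residual: beta {res_true.beta:+5.2f}"
              f" (p = {res_true.p:.2g})")
    pd.DataFrame(rows).to_csv(RESULTS / "association.tsv", sep="\t",
                              index=False)

    tag = "rs764154313"
    before = [r for r in rows if r["snp"] == tag][0]
    hastening = before["beta_years"] < 0
    eliminated = before["p_true_cag"] > 0.01
    print(f"\nCAA-loss tag {tag}: artifact "
          f"{'present' if hastening else 'absent'} before correction "
          f"(p = {before['p']:.2g}), "
          f"{'eliminated' if eliminated else 'NOT eliminated'} after "
          f"(p = {before['p_true_cag']:.2g})")


if __name__ == "__main__":
    main()
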