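"""Stage 3 — outcome-driven risk stratification.

Searches survival-time cut-offs, maximising the two-group log-rank
statistic, to define the survival endpoint used by the classifier, and
quantifies by simulation how optimistic the unadjusted p-value of a
maximally selected statistic is.  Writes ``results/stratification.json``.
"""

import json
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from irsurv.spectra_io import read_cohort
from irsurv.stratify import null_calibration, stratify_by_outcome


def main() -> None:
    cohort = read_cohort(cfg.DATA_DIR / "cohort.tsv")
    result = stratify_by_outcome(cohort, min_group_size=3)

    calibration = null_calibration(
        n_patients=len(cohort), n_simulations=200, seed=cfg.ROOT_SEED
    )
    exceedance = float((calibration["statistic"] > 3.841458820694124).mean())

    payload = {
        "cutoff_months": result.cutoff_months,
        "statistic": result.statistic_at_cutoff,
        "p_value_unadjusted": result.p_value_at_cutoff,
        "n_high": int((result.assignments == "high").sum()),
        "n_low": int((result.assignments == "low").sum()),
        "n_excluded": int((result.assignments == "excluded").sum()),
        "assignments": result.assignments.to_dict(),
        "null_exceedance_of_chi2_95pct": exceedance,
        "candidate_profile": result.candidate_profile.to_dict(orient="records"),
    }
    (cfg.RESULTS / "stratification.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )

    print(f"survival cut-off: {result.cutoff_months:.2f} months "
          f"(log-rank statistic {result.statistic_at_cutoff:.2f}, "
          f"unadjusted p = {result.p_value_at_cutoff:.2e})")
    print(f"  groups: {payload['n_high']} high / {payload['n_low']} low / "
          f"{payload['n_excluded']} excluded (censored before cut-off)")
    print(f"  caution: under a one-class null the maximised statistic exceeds "
          f"the chi-squared(1) 95% quantile in {exceedance:.0%} of simulations — "
          f"the unadjusted p-value is optimistic by construction")


if __name__ == "__main__":
    main()
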