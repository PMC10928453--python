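"""Stage 4 — PCA + logistic classification with bootstrap OOB evaluation.

Labels each patient by the survival endpoint from stage 3, reduces the
fingerprint spectra to seven principal components, fits a ridge-stabilised
logistic regression per bootstrap replicate (patients resampled with
replacement), and evaluates AUROC / sensitivity / specificity on the
out-of-bag patients.  Patient prediction scores are the median datapoint
probability under the full-data model.  Writes ``results/classification.json``
and the scored cohort table.
"""

import json
import sys
from importlib import import_module
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
cfg = import_module("00_config")

from irsurv.classify import bootstrap_evaluate
from irsurv.preprocess import read_dataset
from irsurv.spectra_io import read_cohort, write_cohort_table
from irsurv.stratify import label_endpoint


def main() -> None:
    dataset = read_dataset(cfg.RESULTS / "dataset.tsv")
    cohort = read_cohort(cfg.DATA_DIR / "cohort.tsv")
    strat = json.loads((cfg.RESULTS / "stratification.json").read_text())
    cutoff = strat["cutoff_months"]

    labels = label_endpoint(cohort, cutoff)
    summary, scores = bootstrap_evaluate(
        dataset, labels, n_replicates=cfg.N_REPLICATES, seed=cfg.CLASSIFY_SEED
    )

    scored = cohort.copy()
    scored["score"] = scored["patient_id"].astype(str).map(scores)
    write_cohort_table(scored, cfg.RESULTS / "cohort_scored.tsv")
    payload = {
        "cutoff_months": cutoff,
        "n_labelled_patients": int(len(labels)),
        "n_replicates": summary.n_replicates,
        "median_auroc": summary.median_auroc,
        "median_sensitivity": summary.median_sensitivity,
        "median_specificity": summary.median_specificity,
        "dispersion_half_iqr": summary.dispersion,
        "patient_scores": scores.to_dict(),
    }
    (cfg.RESULTS / "classification.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )

    d = summary.dispersion
    print(f"endpoint: death within {cutoff:.2f} months "
          f"({int(labels.sum())} high / {int((1 - labels).sum())} low labelled)")
    print(f"bootstrap OOB over {summary.n_replicates} replicates:")
    print(f"  median AUROC       {summary.median_auroc:.3f} (±{d['auroc']:.3f} half-IQR)")
    print(f"  median sensitivity {summary.median_sensitivity:.3f} (±{d['sensitivity']:.3f})")
    print(f"  median specificity {summary.median_specificity:.3f} (±{d['specificity']:.3f})")
    print(f"scored cohort → {cfg.RESULTS / 'cohort_scored.tsv'}")


if __name__ == "__main__":
    main()
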