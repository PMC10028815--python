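#!/usr/bin/env python
"""Independent single-predictor MIMIC fits for every region x metric.

One model per predictor (162 in total): the region's metric predicts the
latent cognitive factor on its own.  The table of standardized paths, Wald
tests and Benjamini-Hochberg adjusted p-values is the tabular analogue of
per-metric brain maps.
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from mimiclasso import cohort as ch
from mimiclasso import io as cio
from mimiclasso import pipeline as pl
from mimiclasso.model import mimic_spec

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    contract = cio.ColumnContract(indicators=ch.DEFAULT_INDICATORS,
                                  covariates=("tiv", "sex", "age"))
    data = cio.read_cohort(ROOT / "cohorts" / "cohort_partial.tsv", contract)
    preds = pl._brain_predictors(data)
    scan = pl.per_predictor_scan(data, mimic_spec(ch.DEFAULT_INDICATORS,
                                                  preds))
    scan = scan.sort_values("beta_std", ascending=False)
    print("strongest standardized paths:")
    print(scan.head(10)[["beta_std", "se", "p", "p_bh"]].round(4))
    n_sig = int((scan["p_bh"] < 0.05).sum())
    print(f"\n{n_sig} of {len(scan)} predictors significant after "
          f"Benjamini-Hochberg at 5%")
    cio.write_reports({"per_predictor_scan": scan}, ROOT / "scan")
    print(f"wrote results to {ROOT / 'scan'}")


if __name__ == "__main__":
    main()
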