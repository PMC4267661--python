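"""Saturation of the strongly-regulated proportion with tissue number.

Subsamples k of the 16 tissues, reruns testability + permutation test +
classification per subset, and fits the two saturating models to the
mean curve; the exponential model's asymptote is the inferred upper
bound on the regulated proportion.
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from common import PIPE_CONFIG, RESULTS  # noqa: E402

from gynngy.pipeline import run_extrapolate  # noqa: E402


def main() -> None:
    cfg = PIPE_CONFIG
    curve_path = run_extrapolate(
        cfg,
        str(RESULTS / "site_counts.tsv"),
        str(RESULTS / "catalog.tsv"),
        str(RESULTS),
        n_permutations=2000,
    )
    curve = pd.read_csv(curve_path, sep="\t")
    print(curve.to_string(index=False))
    fits = pd.read_csv(RESULTS / "extrapolation_fits.tsv", sep="\t")
    if not fits.empty:
        print(fits.to_string(index=False))
        best = fits[fits.best]
        print(
            f"inferred upper bound of the strongly regulated proportion: "
            f"{best.iloc[0].asymptote:.3f} (model {best.iloc[0].model})"
        )


if __name__ == "__main__":
    main()
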