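"""Quantify Evans-Blue extravasation on synthetic rasters and fit the
two-phase decay of leakage over time.

Synthetic coronal sections (labelled synthetic: no microscope data is
shipped) contain a bright leak region over a dim background; pixels with
intensity strictly above 100 count as extravasation and the integrated
density is summed over a fixed cortical ROI.  Per-sex mean integrated
densities across the five timepoints are then fit with the two-phase
exponential decay, with the male series built to decline near-linearly
(slow phase dominant) and the female series to drop fast early (fast
phase dominant), mirroring the sex-specific leakage dynamics the
pipeline is designed to resolve.

Writes results/leakage_metrics.csv and results/decay_fits.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bbbtraj.leakage import (
    IntensityImage,
    extravasation_area,
    fit_two_phase_decay,
    integrated_density,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260921
TIMES_H = {"1h": 1.0, "6h": 6.0, "1d": 24.0, "3d": 72.0, "7d": 168.0}

# per-sex decay truth for the synthetic series (arbitrary density units)
SERIES = {
    "male": dict(P=20.0, A_fast=30.0, k_fast=0.5, A_slow=60.0, k_slow=0.012),
    "female": dict(P=20.0, A_fast=80.0, k_fast=0.25, A_slow=15.0, k_slow=0.012),
}


def synthetic_section(rng: np.random.Generator, leak_level: float) -> IntensityImage:
    """A 64x64 synthetic coronal section: background ~N(60, 10), one
    rectangular leak region whose brightness scales with leak_level."""
    pixels = rng.normal(60.0, 10.0, (64, 64)).clip(0, 255)
    size = 6 + int(leak_level / 10)
    pixels[20:20 + size, 24:24 + size] += leak_level
    roi = np.zeros_like(pixels, dtype=bool)
    roi[8:56, 8:56] = True  # fixed cortical ROI
    return IntensityImage(pixels.clip(0, 255), roi)


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for sex, truth in SERIES.items():
        for tp, t in TIMES_H.items():
            leak = (
                truth["A_fast"] * np.exp(-truth["k_fast"] * t)
                + truth["A_slow"] * np.exp(-truth["k_slow"] * t)
            )
            img = synthetic_section(rng, leak_level=leak)
            count, frac = extravasation_area(img)
            rows.append(
                {
                    "sex": sex, "timepoint": tp, "hours": t,
                    "extravasation_pixels": count,
                    "extravasation_fraction": round(frac, 4),
                    "integrated_density": round(integrated_density(img), 1),
                }
            )
    metrics = pd.DataFrame(rows)
    metrics.to_csv(RESULTS / "leakage_metrics.csv", index=False)
    print(metrics.to_string(index=False))

    print("\ntwo-phase decay fits of the noiseless per-sex density series:")
    fits = []
    t = np.array(list(TIMES_H.values()) + [3.0, 12.0, 48.0])  # interior support
    for sex, truth in SERIES.items():
        y = (
            truth["P"]
            + truth["A_fast"] * np.exp(-truth["k_fast"] * t)
            + truth["A_slow"] * np.exp(-truth["k_slow"] * t)
        )
        fit = fit_two_phase_decay(t, y)
        fits.append(
            {
                "sex": sex, "plateau": fit.plateau,
                "A_fast": fit.a_fast, "k_fast": fit.k_fast,
                "A_slow": fit.a_slow, "k_slow": fit.k_slow,
                "rss": fit.rss, "single_phase_rss": fit.single_phase.rss,
                "converged": fit.converged,
            }
        )
        print(
            f"  {sex:<7} P={fit.plateau:6.2f}  "
            f"A_fast={fit.a_fast:6.2f} k_fast={fit.k_fast:.4f}  "
            f"A_slow={fit.a_slow:6.2f} k_slow={fit.k_slow:.4f}  "
            f"(truth P={truth['P']}, kf={truth['k_fast']}, ks={truth['k_slow']})"
        )
    pd.DataFrame(fits).to_csv(RESULTS / "decay_fits.csv", index=False)


if __name__ == "__main__":
    main()
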