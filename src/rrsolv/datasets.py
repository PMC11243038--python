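"""Packaged reference data.

``table1.csv`` holds the published Raman (1064 nm) and resonance-Raman
(266 nm, 210 nm) cross-sections (cm² cm mol⁻¹ sr⁻¹) of nine vibrations of
caffeine in aqueous solution, together with the published enhancement
factors (RR/Raman) at both excitation wavelengths and the peak positions
(single frame / ensemble average, with the standard deviation of the
averaged position).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .spectra import (Spectrum, W0_RAMAN_CM, W0_RR_CM, W0_RR_UV_CM)


def load_table1() -> pd.DataFrame:
    """The packaged cross-section/enhancement reference table."""
    with resources.files("rrsolv.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)


def table1_stick_spectra() -> dict[str, Spectrum]:
    """Reference cross-sections as mode-labelled stick spectra.

    Keys: ``raman`` (1064 nm), ``rr266`` and ``rr210``.  Axes use the
    ensemble-averaged peak positions.
    """
    df = load_table1().sort_values("position_avg_cm")
    axis = df["position_avg_cm"].to_numpy(float)
    labels = tuple(df["label"])
    mk = lambda col, w0, kind: Spectrum(
        axis=axis, intensities=df[col].to_numpy(float), kind=kind,
        w0_cm=w0, is_sticks=True, labels=labels,
        intensity_unit="cm2 cm mol-1 sr-1")
    return {
        "raman": mk("raman_1064", W0_RAMAN_CM, "raman"),
        "rr266": mk("rr_266", W0_RR_CM, "rr"),
        "rr210": mk("rr_210", W0_RR_UV_CM, "rr"),
    }
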