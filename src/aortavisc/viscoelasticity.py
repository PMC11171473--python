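"""Dynamic elastic modulus and the equivalent blood-pressure axis.

The resonance features of a loaded strip are converted into the two
viscoelastic characteristics of interest:

* the dynamic modulus of elasticity

      E' = (2 pi f0)^2 * m * (L0 + dL) / S

  with m the suspended oscillating mass, L0 the initial strip length, dL
  the static elongation under load and S the cross-section area;

* the equivalent blood pressure, i.e. the intraluminal pressure of a
  cylindrical vessel whose wall stress matches the stress the suspended
  mass imposes on the strip.  By the thin-walled Laplace law the wall
  tension per unit axial length of a vessel of radius r_v at pressure P is
  P*r_v, while the hanging mass loads the strip of width b with m*g/b, so

      p = m * g / (b * r_v)        (converted to mmHg).

  The mapping is deliberately isolated in a single function with a
  configurable r_v so any alternative calibration can be expressed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "G_STANDARD",
    "MMHG_PA",
    "StripGeometry",
    "LoadStep",
    "dynamic_modulus",
    "mass_to_equivalent_pressure",
    "assemble_points",
]

#: Standard gravity, m/s^2.
G_STANDARD = 9.80665
#: 1 mmHg in Pa.
MMHG_PA = 133.322


@dataclasses.dataclass(frozen=True)
class StripGeometry:
    """Geometry of one strip preparation (SI units).

    L0: initial length (m); b: width (m); h: thickness (m);
    r_v: radius of the source vessel (m), used by the pressure mapping.
    The cross-section S is always b*h.
    """

    L0: float
    b: float
    h: float
    r_v: float

    def __post_init__(self) -> None:
        for name in ("L0", "b", "h", "r_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"geometry field {name} must be > 0")

    @property
    def S(self) -> float:
        """Cross-section area b*h, m^2."""
        return self.b * self.h


@dataclasses.dataclass(frozen=True)
class LoadStep:
    """One of the four discrete loading levels."""

    index: int
    m_ring: float
    m_osc: float
    elongation: float
    equivalent_pressure: float

    def __post_init__(self) -> None:
        if self.m_ring <= 0 or self.m_osc <= 0:
            raise ValueError("masses must be > 0")
        if self.elongation < 0:
            raise ValueError("elongation must be >= 0")


def dynamic_modulus(f0, m, L0, dL, S):
    """Dynamic modulus of elasticity E' = (2 pi f0)^2 m (L0 + dL) / S, in Pa.

    Accepts scalars or arrays (broadcasting).  f0 in Hz, m in kg, lengths in
    m, S in m^2; dL may be 0 (unloaded limit), everything else must be > 0.
    """
    f0 = np.asarray(f0, dtype=float)
    m = np.asarray(m, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    dL = np.asarray(dL, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(f0 <= 0) or np.any(m <= 0) or np.any(L0 <= 0) or np.any(S <= 0):
        raise ValueError("f0, m, L0 and S must all be > 0")
    if np.any(dL < 0):
        raise ValueError("elongation dL must be >= 0")
    out = (2.0 * np.pi * f0) ** 2 * m * (L0 + dL) / S
    return float(out) if out.ndim == 0 else out


def mass_to_equivalent_pressure(m_ring, geometry: StripGeometry):
    """Equivalent blood pressure (mmHg) of a suspended ring mass.

    Thin-walled Laplace equivalence p = m g / (b r_v); strictly increasing
    in the mass.  Scalar or array input.
    """
    m_ring = np.asarray(m_ring, dtype=float)
    if np.any(m_ring < 0):
        raise ValueError("ring mass must be >= 0")
    p_pa = m_ring * G_STANDARD / (geometry.b * geometry.r_v)
    out = p_pa / MMHG_PA
    return float(out) if out.ndim == 0 else out


def assemble_points(features: pd.DataFrame, geometry: StripGeometry,
                    manifest: dict, *,
                    drop_failed_qc: bool = False) -> pd.DataFrame:
    """Join resonance features with the loading/protocol metadata.

    ``features`` needs columns subject, stage, mass_index, f0_Hz and
    (optionally) qc_flags; ``manifest`` is the study manifest whose
    ``measurements`` entries carry m_osc_kg, dL_m and p_mmHg per
    (subject, stage, mass_index).  Every feature row must match exactly one
    measurement; orphans on either side of the join raise with the list of
    offending keys.  Rows with non-empty qc_flags are kept (flagged) unless
    ``drop_failed_qc`` is set; downstream statistics exclude them either way.

    Returns the tidy observation table with one row per measurement:
    subject, group, stage, mass_index, p_mmHg, f0_Hz, Eprime_Pa, Eprime_MPa,
    qc_flags.
    """
    required = {"subject", "stage", "mass_index", "f0_Hz"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"features table lacks columns {sorted(missing)}")
    if features.empty:
        import warnings

        warnings.warn("empty features table; assembling zero points")
        return pd.DataFrame(columns=["subject", "group", "stage", "mass_index",
                                     "p_mmHg", "f0_Hz", "Eprime_Pa",
                                     "Eprime_MPa", "qc_flags"])

    key = ["subject", "stage", "mass_index"]
    feat = features.drop(columns=["group"], errors="ignore").copy()
    feat["mass_index"] = feat["mass_index"].astype(int)
    dup = feat.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            "duplicated measurement ids in features table: "
            f"{feat.loc[dup, key].to_records(index=False).tolist()}")

    meta = pd.DataFrame(manifest["measurements"])
    meta = meta[["subject", "group", "stage", "mass_index", "m_osc_kg",
                 "dL_m", "p_mmHg"]]
    merged = feat.merge(meta, on=key, how="left", indicator=True)
    orphans = merged["_merge"] == "left_only"
    if orphans.any():
        raise ValueError(
            "feature rows without a manifest entry: "
            f"{merged.loc[orphans, key].to_records(index=False).tolist()}")
    merged = merged.drop(columns="_merge")

    if "qc_flags" not in merged.columns:
        merged["qc_flags"] = ""
    merged["qc_flags"] = merged["qc_flags"].fillna("")
    usable = merged["f0_Hz"].to_numpy(dtype=float) > 0
    usable &= np.isfinite(merged["f0_Hz"].to_numpy(dtype=float))
    merged["Eprime_Pa"] = np.nan
    merged.loc[usable, "Eprime_Pa"] = dynamic_modulus(
        merged.loc[usable, "f0_Hz"].to_numpy(),
        merged.loc[usable, "m_osc_kg"].to_numpy(),
        geometry.L0,
        merged.loc[usable, "dL_m"].to_numpy(),
        geometry.S)
    merged["Eprime_MPa"] = merged["Eprime_Pa"] / 1e6
    if drop_failed_qc:
        merged = merged[merged["qc_flags"] == ""]
    cols = ["subject", "group", "stage", "mass_index", "p_mmHg",
            "f0_Hz", "Eprime_Pa", "Eprime_MPa", "qc_flags"]
    return merged[cols].reset_index(drop=True)
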