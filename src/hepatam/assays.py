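"""Synthetic co-culture assay readouts and the calibration mapping from
readouts to simulation parameters.

The wet-lab stage this package replaces measured, by ELISA on indirect
(transwell) co-cultures of bone marrow-derived macrophages with tumor
cells, the fold structure of TNF-α and TGF-β1 across macrophage
activation states (naive / M1 / M2) and tumor types (none / primary /
metastatic):

* TNF-α is ~5-fold higher with M1- than with M2-activated macrophages
  in every tumor condition;
* the metastatic co-culture induces ~10-fold more TNF-α with M1 than
  the primary co-culture;
* TGF-β1 is essentially flat across conditions, with a slight (≤1.3x)
  elevation for primary cells with M1.

Only these ratios enter the simulation: absolute units are arbitrary
and production rates are anchored to the configured baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .config import ECMParams, MDEParams

MACROPHAGE_STATES = ("naive", "M1", "M2")
TUMOR_CONDITIONS = ("none", "primary", "metastatic")


class CalibrationError(ValueError):
    pass


@dataclass
class ElisaPanel:
    """One condition of the synthetic co-culture ELISA."""

    macrophage_state: str     # naive | M1 | M2
    tumor: str                # none | primary | metastatic
    tnf_level: float          # configured condition mean (arbitrary units)
    tgf_level: float
    tnf_replicates: list[float] = field(default_factory=list)
    tgf_replicates: list[float] = field(default_factory=list)

    @property
    def tnf_mean(self) -> float:
        return float(np.mean(self.tnf_replicates)) if self.tnf_replicates else self.tnf_level

    @property
    def tgf_mean(self) -> float:
        return float(np.mean(self.tgf_replicates)) if self.tgf_replicates else self.tgf_level


@dataclass
class CalibrationResult:
    tnf_production_primary: float
    tnf_production_metastatic: float
    tgf_production: float
    tnf_metastatic_fold: float
    tnf_m1_m2_fold: float
    ecm_rate_pairs: dict[str, tuple[float, float]] | None = None


# condition-mean structure of the synthetic assay (arbitrary units)
_TNF_M2_BASE = {"none": 10.0, "primary": 20.0, "metastatic": 200.0}
_TNF_M1_OVER_M2 = 5.0
_TGF_BASE = 50.0
_TGF_PRIMARY_M1_FACTOR = 1.2


def _lognormal_draws(rng: np.random.Generator, mean: float, cv: float,
                     n: int) -> list[float]:
    """Mean-preserving lognormal replicates with coefficient of variation cv."""
    if cv == 0.0:
        return [mean] * n
    s2 = np.log1p(cv * cv)
    draws = mean * np.exp(rng.normal(-0.5 * s2, np.sqrt(s2), size=n))
    return draws.tolist()


def generate_elisa(rng: np.random.Generator, noise_cv: float = 0.15,
                   n_replicates: int = 6) -> list[ElisaPanel]:
    """Generate the 3 × 3 panel of synthetic ELISA conditions.

    Mean structure: within each tumor condition TNF-α is 5x higher for
    M1 than M2 (naive matches the M2 level); the metastatic condition
    is 10x the primary; TGF-β1 is constant except a 1.2x elevation for
    primary-with-M1. Replicates carry lognormal noise of the given CV.
    """
    if not (0.0 <= noise_cv <= 0.5):
        raise CalibrationError("noise_cv must lie in [0, 0.5]")
    if n_replicates < 3:
        raise CalibrationError("at least 3 replicates per condition")
    panels = []
    for tumor in TUMOR_CONDITIONS:
        for state in MACROPHAGE_STATES:
            base = _TNF_M2_BASE[tumor]
            tnf = base * _TNF_M1_OVER_M2 if state == "M1" else base
            tgf = _TGF_BASE
            if state == "M1" and tumor == "primary":
                tgf *= _TGF_PRIMARY_M1_FACTOR
            panels.append(ElisaPanel(
                macrophage_state=state, tumor=tumor,
                tnf_level=tnf, tgf_level=tgf,
                tnf_replicates=_lognormal_draws(rng, tnf, noise_cv, n_replicates),
                tgf_replicates=_lognormal_draws(rng, tgf, noise_cv, n_replicates),
            ))
    return panels


def _panel(panels: list[ElisaPanel], state: str, tumor: str) -> ElisaPanel:
    for p in panels:
        if p.macrophage_state == state and p.tumor == tumor:
            return p
    raise CalibrationError(f"missing ELISA condition: {state} x {tumor}")


def calibrate_cytokines(panels: list[ElisaPanel],
                        baseline_tnf_production: float = 20.0,
                        baseline_tgf_production: float = 10.0) -> CalibrationResult:
    """Map assay fold structure onto cytokine production rates.

    The metastatic TNF-α production rate is the primary baseline scaled
    by the measured metastatic:primary TNF fold. The fold is pooled as
    the geometric mean of the per-state (naive/M1/M2) ratios of
    replicate means: the co-culture induction acts on every macrophage
    state, so pooling triples the effective replication without biasing
    the noiseless value. TGF-β1 production is kept identical across
    tumor types, anchored to the baseline and scaled by the
    geometric-mean TGF level relative to the no-tumor naive reference.
    """
    ratios = []
    for state in MACROPHAGE_STATES:
        prim = _panel(panels, state, "primary").tnf_mean
        met = _panel(panels, state, "metastatic").tnf_mean
        if prim <= 0 or met <= 0:
            raise CalibrationError(f"TNF means must be positive ({state})")
        ratios.append(met / prim)
    fold = float(np.exp(np.mean(np.log(ratios))))

    m1m2 = []
    for tumor in TUMOR_CONDITIONS:
        m1 = _panel(panels, "M1", tumor).tnf_mean
        m2 = _panel(panels, "M2", tumor).tnf_mean
        if m2 <= 0:
            raise CalibrationError(f"M2 TNF mean must be positive ({tumor})")
        m1m2.append(m1 / m2)
    tnf_m1_m2_fold = float(np.exp(np.mean(np.log(m1m2))))

    ref = _panel(panels, "naive", "none").tgf_mean
    tgf_means = [_panel(panels, s, t).tgf_mean
                 for t in TUMOR_CONDITIONS for s in MACROPHAGE_STATES]
    if ref <= 0 or min(tgf_means) <= 0:
        raise CalibrationError("TGF means must be positive")
    tgf_scale = float(np.exp(np.mean(np.log(tgf_means))) / ref)

    return CalibrationResult(
        tnf_production_primary=baseline_tnf_production,
        tnf_production_metastatic=baseline_tnf_production * fold,
        tgf_production=baseline_tgf_production * tgf_scale,
        tnf_metastatic_fold=float(fold),
        tnf_m1_m2_fold=tnf_m1_m2_fold,
    )


def normalize_migration(counts, control_counts):
    """Transwell counts divided by the mean of their control group."""
    control = np.asarray(control_counts, dtype=float)
    if control.size == 0 or control.mean() <= 0:
        raise CalibrationError("control group mean must be positive")
    return (np.asarray(counts, dtype=float) / control.mean()).tolist()


def _mde_fixed_point(mde: MDEParams) -> float:
    """0-D fixed point of the MDE balance (production vs decay)."""
    denom = mde.lambda_production_M + mde.lambda_decay_M
    return mde.lambda_production_M / denom if denom > 0 else 0.0


def ecm_steady_state(lambda_prod: float, lambda_deg: float, ecm: ECMParams,
                     m_star: float) -> float:
    """Root of the scalar matrix balance
    λ_prod/(1+k_p E) = λ_deg E m*/(1+k_d E)."""
    def residual(E: float) -> float:
        return (lambda_prod / (1.0 + ecm.k_p * E)
                - lambda_deg * E * m_star / (1.0 + ecm.k_d * E))

    if lambda_deg * m_star <= 0:
        raise CalibrationError("degradation side vanishes; no finite steady state")
    hi = 1.0
    while residual(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise CalibrationError("no finite ECM steady state found")
    return float(brentq(residual, 0.0, hi, xtol=1e-12))


def calibrate_ecm(target_density_ratio: float,
                  ecm: ECMParams | None = None,
                  mde: MDEParams | None = None) -> dict[str, tuple[float, float]]:
    """Production/degradation pairs giving the requested transitional:
    control steady-state density ratio.

    The control pair is the configured default; the transitional pair
    keeps the production rate and lowers degradation until the scalar
    steady state of the matrix balance (with the enzyme fixed at its
    0-D fixed point) sits at ``target_density_ratio`` times the control
    density, verified to 1e-4.
    """
    if target_density_ratio < 1.0:
        raise CalibrationError("target_density_ratio must be >= 1 (tECM denser)")
    ecm = ecm or ECMParams()
    mde = mde or MDEParams()
    m_star = _mde_fixed_point(mde)
    lam_p = ecm.lambda_production_E
    lam_d_c = ecm.lambda_degradation_E
    if target_density_ratio == 1.0:
        return {"cECM": (lam_p, lam_d_c), "tECM": (lam_p, lam_d_c)}
    e_c = ecm_steady_state(lam_p, lam_d_c, ecm, m_star)
    e_t = target_density_ratio * e_c
    # closed-form degradation rate hitting E* = e_t, then verify by residual
    lam_d_t = lam_p * (1.0 + ecm.k_d * e_t) / ((1.0 + ecm.k_p * e_t) * e_t * m_star)
    achieved = ecm_steady_state(lam_p, lam_d_t, ecm, m_star)
    if abs(achieved - e_t) > 1e-4 * max(1.0, e_t):
        raise CalibrationError(
            f"requested density ratio unattainable (achieved E*={achieved:.6g})")
    return {"cECM": (lam_p, lam_d_c), "tECM": (lam_p, lam_d_t)}
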