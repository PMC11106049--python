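"""Synthetic inputs with known ground truth.

Two generators stand in for the expensive upstream stages of the workflow:

* :func:`gen_ensemble` emulates quantum-chemistry output — a conformer
  ensemble of known chirality, each conformer carrying ~95 electronic
  transitions with signed rotatory strengths and an exponentially
  distributed relative Gibbs energy.  Requesting the mirror chirality with
  the same seed returns the identical ensemble with every rotatory
  strength negated, so enantiomer pairs are exact by construction.
* :func:`gen_peak_tables` emulates multi-condition LC/MS feature tables in
  the style of a five-condition OSMAC comparison (Pv0/PvMg/PvFe/PvZn/PvNi):
  shared features with log-normal area noise, condition-specific
  presence/absence features, and one condition whose every peak area is
  globally scaled (default 5x, with extra condition-specific features,
  mirroring an iron-supplemented outlier extract).

All draws are fixed by (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .conformers import Conformer, ElectronicTransition, Ensemble
from .ecd_sim import BandShapeParams, SpectrumGrid, simulate_ensemble_ecd
from .lcms_profiles import Peak, PeakTable

__all__ = [
    "EnsembleSpec",
    "ConditionSpec",
    "gen_ensemble",
    "gen_experimental_spectrum",
    "gen_peak_tables",
]

#: Default OSMAC condition labels: control plus four metal-salt additions.
DEFAULT_CONDITIONS = ("Pv0", "PvMg", "PvFe", "PvZn", "PvNi")


@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a synthetic conformer ensemble.

    delta_g_scale is the mean of the exponential spread of relative Gibbs
    energies (kcal/mol); 1.5 keeps several conformers populated below the
    4 kcal/mol cutoff, as in a typical flexible natural product.
    """

    n_conformers: int = 8
    n_transitions: int = 95
    delta_g_scale: float = 1.5
    wavelength_range: Tuple[float, float] = (185.0, 320.0)
    rotatory_strength_scale: float = 30.0  # 1e-40 cgs
    chirality: str = "R"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers < 1 or self.n_transitions < 1:
            raise ValueError("counts must be >= 1")
        if self.chirality not in ("R", "S"):
            raise ValueError("chirality must be 'R' or 'S'")


@dataclass(frozen=True)
class ConditionSpec:
    """Recipe for multi-condition synthetic peak tables.

    ``n_specific`` gives the number of condition-exclusive features per
    label; the outlier condition both gains extra exclusive features and
    has all its areas multiplied by ``outlier_multiplier``.
    """

    labels: Tuple[str, ...] = DEFAULT_CONDITIONS
    n_shared_features: int = 12
    n_specific: Optional[Dict[str, int]] = None
    outlier: str = "PvFe"
    outlier_multiplier: float = 5.0
    area_cv: float = 0.3
    rt_range: Tuple[float, float] = (9.0, 55.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outlier_multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if self.n_specific is None:
            spec = {lbl: (3 if lbl == self.outlier else 1) for lbl in self.labels}
            object.__setattr__(self, "n_specific", spec)
        if self.outlier not in self.labels:
            raise ValueError(f"outlier {self.outlier!r} not among labels")


def gen_ensemble(spec: EnsembleSpec) -> Ensemble:
    """Draw a chirality-tagged conformer ensemble.

    The chirality label only flips the sign of every rotatory strength;
    energies, wavelengths and magnitudes are identical for both labels at
    a given seed (exact mirror construction).
    """
    rng = np.random.default_rng(spec.seed)
    dg = rng.exponential(spec.delta_g_scale, spec.n_conformers) if spec.delta_g_scale > 0 \
        else np.zeros(spec.n_conformers)
    dg = dg - dg.min()
    sign = 1.0 if spec.chirality == "R" else -1.0
    lo, hi = spec.wavelength_range
    conformers = []
    for i in range(spec.n_conformers):
        wl = rng.uniform(lo, hi, spec.n_transitions)
        r = rng.normal(0.0, spec.rotatory_strength_scale, spec.n_transitions)
        transitions = tuple(
            ElectronicTransition.from_wavelength(w, sign * ri)
            for w, ri in zip(wl, r)
        )
        conformers.append(Conformer(f"conf-{i:02d}", float(dg[i]), transitions))
    return Ensemble(
        conformers,
        metadata={"chirality": spec.chirality, "seed": spec.seed, "synthetic": True},
    )


def gen_experimental_spectrum(
    ensemble: Ensemble,
    params: BandShapeParams = BandShapeParams(),
    noise_fraction: float = 0.05,
    baseline_drift: float = 0.0,
    seed: int = 0,
) -> SpectrumGrid:
    """Simulate a measured CD spectrum from a known ensemble.

    The Boltzmann-averaged spectrum gets additive Gaussian noise with
    sigma = noise_fraction x peak |d_eps|, plus an optional slow quadratic
    baseline of amplitude baseline_drift x peak |d_eps|.  The generating
    chirality stays in the metadata as ground truth.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    clean = simulate_ensemble_ecd(ensemble, params)
    peak = float(np.max(np.abs(clean.delta_epsilon)))
    rng = np.random.default_rng(seed)
    values = clean.delta_epsilon.copy()
    if noise_fraction > 0 and peak > 0:
        values = values + rng.normal(0.0, noise_fraction * peak, values.shape)
    if baseline_drift > 0 and peak > 0:
        x = np.linspace(-1.0, 1.0, values.size)
        coeffs = rng.normal(0.0, 1.0, 3)
        baseline = coeffs[0] + coeffs[1] * x + coeffs[2] * x * x
        baseline *= baseline_drift * peak / max(np.max(np.abs(baseline)), 1e-12)
        values = values + baseline
    meta = dict(clean.metadata)
    meta.update(provenance="experimental", noise_fraction=noise_fraction,
                baseline_drift=baseline_drift, noise_seed=seed)
    return SpectrumGrid(clean.wavelengths, values, meta)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def gen_peak_tables(spec: ConditionSpec) -> List[PeakTable]:
    """Draw one peak table per cultivation condition.

    Shared features appear in every condition with log-normal area noise at
    the requested CV around a common feature-specific base area (itself
    log-normally spread over ~1.5 orders of magnitude).  Condition-specific
    features appear only in their own condition.  Every area of the outlier
    condition is multiplied by ``outlier_multiplier``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.rt_range
    sigma = _lognormal_sigma(spec.area_cv)

    def draw_feature(rng: np.random.Generator) -> Tuple[float, float, float]:
        rt = float(rng.uniform(lo, hi))
        mz = float(rng.uniform(200.0, 600.0))
        base_area = float(rng.lognormal(math.log(100.0), 1.0))
        return rt, mz, base_area

    shared = [(f"F{j:03d}", *draw_feature(rng)) for j in range(spec.n_shared_features)]
    specific = {
        lbl: [(f"{lbl}_S{j}", *draw_feature(rng)) for j in range(spec.n_specific[lbl])]
        for lbl in spec.labels
    }

    tables = []
    for lbl in spec.labels:
        mult = spec.outlier_multiplier if lbl == spec.outlier else 1.0
        peaks = []
        for fid, rt, mz, base in [*shared, *specific[lbl]]:
            area = base * float(rng.lognormal(0.0, sigma)) * mult
            peaks.append(Peak(fid, rt, area, mz))
        tables.append(PeakTable(lbl, peaks))
    return tables
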