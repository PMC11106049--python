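"""ECD spectrum simulation from TDDFT transition lists.

Each electronic transition *i* (excitation energy ``E_i`` in eV, rotatory
strength ``R_i`` in 1e-40 cgs units) contributes a Gaussian band built in
the energy domain,

    d_eps_i(E) = E_i * R_i / (c0 * sqrt(pi) * sigma) * exp(-((E - E_i)/sigma)^2)

with the standard chiroptical normalization constant c0 = 2.297e-39 and
bandwidth sigma = zeta (default 0.16 eV, interpreted as the 1/e half-width;
an FWHM interpretation is available via ``zeta_is_fwhm``).  The summed
curve is evaluated on a uniform wavelength grid, red-shifted by
``delta_lambda`` (default +1 nm), Boltzmann-averaged over conformers, and
optionally normalized to the positive reference band (scaled spectrum:
d_eps_sc(lambda) = d_eps(lambda) / |d_eps(lambda_peak)|).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .conformers import (
    EV_NM,
    Conformer,
    Ensemble,
    WeightVector,
    boltzmann_weights,
    filter_by_delta_g,
    rereference_energies,
)

__all__ = [
    "C0_CGS",
    "BandShapeParams",
    "SpectrumGrid",
    "ScaledSpectrum",
    "simulate_conformer_ecd",
    "average_ensemble_ecd",
    "simulate_ensemble_ecd",
    "enantiomer_ecd",
    "mixture_ecd",
    "scale_spectrum",
    "read_spectrum",
    "write_spectrum",
]

#: cgs normalization constant converting E[eV] x R[cgs] Gaussian bands into
#: molar circular dichroism d_eps in 1/(M cm).
C0_CGS = 2.297e-39
#: Rotatory strengths are supplied in units of 1e-40 cgs.
R_UNIT = 1e-40


@dataclass(frozen=True)
class BandShapeParams:
    """Band-shape and grid settings for spectrum simulation.

    zeta: Gaussian bandwidth in eV (1/e half-width unless ``zeta_is_fwhm``).
    delta_lambda: rigid wavelength shift in nm applied to the final curve.
    grid: uniform wavelength grid in nm, default 180-400 at 0.5 nm.
    """

    zeta: float = 0.16
    delta_lambda: float = 1.0
    grid_min: float = 180.0
    grid_max: float = 400.0
    grid_step: float = 0.5
    zeta_is_fwhm: bool = False

    def __post_init__(self) -> None:
        if not self.zeta > 0:
            raise ValueError(f"zeta must be positive, got {self.zeta}")
        if not self.grid_min < self.grid_max:
            raise ValueError("grid_min must be below grid_max")
        if not self.grid_step > 0:
            raise ValueError("grid_step must be positive")

    @property
    def sigma(self) -> float:
        """Gaussian 1/e half-width in eV."""
        if self.zeta_is_fwhm:
            return self.zeta / (2.0 * math.sqrt(math.log(2.0)))
        return self.zeta

    def wavelength_grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class SpectrumGrid:
    """Circular-dichroism curve d_eps(lambda) on a uniform wavelength grid."""

    wavelengths: np.ndarray  # nm, strictly increasing
    delta_epsilon: np.ndarray  # 1/(M cm)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        de = np.asarray(self.delta_epsilon, dtype=float)
        if wl.shape != de.shape or wl.ndim != 1:
            raise ValueError("wavelengths and delta_epsilon must be equal-length 1-d arrays")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "delta_epsilon", de)

    def with_values(self, values: np.ndarray, **meta: object) -> "SpectrumGrid":
        return SpectrumGrid(self.wavelengths, np.asarray(values, dtype=float),
                            {**self.metadata, **meta})

    def same_grid(self, other: "SpectrumGrid") -> bool:
        return (
            self.wavelengths.shape == other.wavelengths.shape
            and bool(np.allclose(self.wavelengths, other.wavelengths, rtol=0, atol=1e-9))
        )


@dataclass(frozen=True)
class ScaledSpectrum(SpectrumGrid):
    """Spectrum divided by |d_eps| at its positive reference band."""

    reference_peak_lambda: float = float("nan")
    reference_peak_magnitude: float = float("nan")


def _band_sum(
    energies_ev: np.ndarray,
    strengths: np.ndarray,
    eval_energies: np.ndarray,
    sigma: float,
) -> np.ndarray:
    pref = energies_ev * strengths * R_UNIT / (C0_CGS * math.sqrt(math.pi) * sigma)
    # (n_transitions, n_grid) Gaussian matrix; ensembles are small enough
    # that the dense outer product is the fastest route
    z = (eval_energies[None, :] - energies_ev[:, None]) / sigma
    return (pref[:, None] * np.exp(-z * z)).sum(axis=0)


def simulate_conformer_ecd(
    conformer: Conformer, params: BandShapeParams = BandShapeParams()
) -> SpectrumGrid:
    """Broaden one conformer's transitions into a d_eps(lambda) curve.

    Bands are Gaussian in energy; the curve is sampled at the energies
    corresponding to the (shift-corrected) wavelength grid, so the final
    spectrum appears shifted by ``delta_lambda`` toward longer wavelengths.
    """
    if len(conformer.transitions) == 0:
        raise ValueError(f"conformer {conformer.id!r} has no transitions")
    wl = params.wavelength_grid()
    source_wl = wl - params.delta_lambda
    if np.any(source_wl <= 0):
        raise ValueError("grid extends below the applied wavelength shift")
    e_grid = EV_NM / source_wl
    e_i = np.array([t.energy_ev for t in conformer.transitions])
    r_i = np.array([t.rotatory_strength for t in conformer.transitions])
    values = _band_sum(e_i, r_i, e_grid, params.sigma)
    meta: Dict[str, object] = {
        "provenance": "calculated",
        "conformer": conformer.id,
        "delta_lambda_nm": params.delta_lambda,
        "zeta_eV": params.zeta,
    }
    covered = (e_i >= e_grid.min() - 3 * params.sigma) & (e_i <= e_grid.max() + 3 * params.sigma)
    if not covered.any():
        meta["warnings"] = ["no transition lies within the grid +- 3 zeta"]
    return SpectrumGrid(wl, values, meta)


def average_ensemble_ecd(
    spectra: Sequence[SpectrumGrid],
    weights: "WeightVector | Sequence[float]",
    conformer_ids: "Sequence[str] | None" = None,
) -> SpectrumGrid:
    """Pointwise Boltzmann-weighted average of per-conformer spectra.

    ``weights`` may be a :class:`WeightVector` (keyed by conformer id, taken
    from each spectrum's metadata unless ``conformer_ids`` is given) or a
    plain sequence aligned with ``spectra``.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    base = spectra[0]
    for s in spectra[1:]:
        if not base.same_grid(s):
            raise ValueError("spectra are on different grids; resample explicitly first")
    if isinstance(weights, WeightVector):
        ids = list(conformer_ids) if conformer_ids is not None else [
            str(s.metadata.get("conformer")) for s in spectra
        ]
        w = np.array(weights.as_list(ids))
    else:
        w = np.asarray(list(weights), dtype=float)
    if w.shape != (len(spectra),):
        raise ValueError("one weight per spectrum required")
    if not math.isclose(float(w.sum()), 1.0, abs_tol=1e-9):
        raise ValueError(f"weights must sum to 1, got {w.sum()}")
    values = sum(wi * s.delta_epsilon for wi, s in zip(w, spectra))
    return SpectrumGrid(base.wavelengths, values, {"provenance": "calculated",
                                                   "averaged_over": len(spectra)})


def simulate_ensemble_ecd(
    ensemble: Ensemble,
    params: BandShapeParams = BandShapeParams(),
    delta_g_cutoff: float = 4.0,
    temperature: "float | None" = None,
) -> SpectrumGrid:
    """Full pipeline: re-reference, apply the dG cutoff, Boltzmann-weight,
    simulate each conformer and average."""
    ens = filter_by_delta_g(rereference_energies(ensemble), delta_g_cutoff)
    w = boltzmann_weights(ens, temperature)
    spectra = [simulate_conformer_ecd(c, params) for c in ens.conformers]
    avg = average_ensemble_ecd(spectra, w, conformer_ids=[c.id for c in ens.conformers])
    meta = dict(avg.metadata)
    meta.update(ensemble.metadata)
    meta["n_conformers"] = len(ens.conformers)
    return replace(avg, metadata=meta)


def enantiomer_ecd(spectrum: SpectrumGrid) -> SpectrumGrid:
    """Mirror-image spectrum: pointwise negation."""
    meta = dict(spectrum.metadata)
    meta["chirality_flipped"] = not bool(meta.get("chirality_flipped", False))
    return SpectrumGrid(spectrum.wavelengths, -spectrum.delta_epsilon, meta)


def mixture_ecd(
    spectra: Sequence[SpectrumGrid], ratios: Sequence[float]
) -> SpectrumGrid:
    """Linear combination modelling a mixture of stereoisomers.

    Ratios are normalized internally; e.g. (70, 30) and (0.7, 0.3) agree.
    """
    if len(spectra) != len(ratios):
        raise ValueError("one ratio per spectrum required")
    r = np.asarray(list(ratios), dtype=float)
    if np.any(r < 0):
        raise ValueError("ratios must be non-negative")
    total = r.sum()
    if total <= 0:
        raise ValueError("at least one ratio must be positive")
    base = spectra[0]
    for s in spectra[1:]:
        if not base.same_grid(s):
            raise ValueError("mixture components must share a grid")
    w = r / total
    values = sum(wi * s.delta_epsilon for wi, s in zip(w, spectra))
    return SpectrumGrid(base.wavelengths, values,
                        {"provenance": "calculated", "mixture_ratios": tuple(w.tolist())})


def scale_spectrum(
    spectrum: SpectrumGrid,
    reference_window: Tuple[float, float] = (205.0, 230.0),
) -> ScaledSpectrum:
    """Normalize to the positive reference band inside ``reference_window``.

    Divides the whole curve by |d_eps(lambda_peak)| where lambda_peak is the
    position of the maximum positive value within the window (default
    205-230 nm, bracketing the characteristic ~216 nm band).
    """
    lo, hi = reference_window
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"reference window {reference_window} outside the spectrum grid")
    window_vals = spectrum.delta_epsilon[mask]
    if window_vals.max() <= 0:
        raise ValueError(
            f"no positive d_eps value in the reference window {reference_window}"
        )
    idx = int(np.argmax(np.where(mask, spectrum.delta_epsilon, -np.inf)))
    peak_lambda = float(spectrum.wavelengths[idx])
    peak_mag = abs(float(spectrum.delta_epsilon[idx]))
    meta = dict(spectrum.metadata)
    meta["provenance"] = "scaled"
    return ScaledSpectrum(
        wavelengths=spectrum.wavelengths,
        delta_epsilon=spectrum.delta_epsilon / peak_mag,
        metadata=meta,
        reference_peak_lambda=peak_lambda,
        reference_peak_magnitude=peak_mag,
    )


def read_spectrum(path: "str | Path") -> SpectrumGrid:
    """Read a two-column (wavelength_nm, delta_epsilon) delimited text file.

    A header line is detected and skipped; comma, tab and whitespace
    delimiters are accepted.  A ``<path>.meta.json`` sidecar, if present,
    populates the metadata.
    """
    path = Path(path)
    rows: List[Tuple[float, float]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except (ValueError, IndexError):
            if rows:
                raise ValueError(f"malformed line in {path}: {line!r}")
            continue  # header
    if not rows:
        raise ValueError(f"no numeric data in {path}")
    rows.sort(key=lambda t: t[0])
    wl, de = zip(*rows)
    meta: Dict[str, object] = {"provenance": "experimental", "source": str(path)}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return SpectrumGrid(np.array(wl), np.array(de), meta)


def write_spectrum(spectrum: SpectrumGrid, path: "str | Path") -> None:
    """Write the two-column text format plus a JSON metadata sidecar."""
    path = Path(path)
    lines = ["wavelength_nm,delta_epsilon"]
    lines += [
        f"{wl:.6g},{de:.10g}"
        for wl, de in zip(spectrum.wavelengths, spectrum.delta_epsilon)
    ]
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(
        {k: v for k, v in spectrum.metadata.items() if isinstance(v, (str, int, float, bool, list, tuple))},
        indent=1,
    ))
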