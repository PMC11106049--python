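"""Quantitative comparison of calculated and experimental ECD spectra.

The visual diagnostics used when assigning absolute configuration —
overlaying scaled curves, comparing the first derivatives
d(d_eps(lambda))/d lambda, and checking that extrema fall at the same
wavelengths — are made numerical here: cosine similarity of the scaled
value vectors, cosine similarity of the derivative vectors, and a count of
extrema matched within a wavelength tolerance.  Candidate stereoisomers
(and two-component mixtures over a ratio grid) are ranked by the combined
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from .ecd_sim import ScaledSpectrum, SpectrumGrid, mixture_ecd, scale_spectrum

__all__ = [
    "DerivativeSpectrum",
    "AssignmentResult",
    "resample_to_common_grid",
    "first_derivative",
    "extrema_positions",
    "similarity_score",
    "match_extrema",
    "assign_configuration",
]


@dataclass(frozen=True)
class DerivativeSpectrum:
    wavelengths: np.ndarray
    derivative: np.ndarray  # d(d_eps)/d lambda, per nm


@dataclass(frozen=True)
class AssignmentResult:
    """One ranked stereochemistry hypothesis."""

    label: str
    curve_similarity: float
    derivative_similarity: float
    combined_similarity: float
    extrema_matched: int
    rank: int
    mixture_ratio: Optional[float] = None
    error: Optional[str] = None

    def as_dict(self) -> Dict[str, object]:
        return {
            "label": self.label,
            "curve_similarity": self.curve_similarity,
            "derivative_similarity": self.derivative_similarity,
            "combined_similarity": self.combined_similarity,
            "extrema_matched": self.extrema_matched,
            "rank": self.rank,
            "mixture_ratio": self.mixture_ratio,
            "error": self.error,
        }


def _median_step(wl: np.ndarray) -> float:
    return float(np.median(np.diff(wl)))


def resample_to_common_grid(
    a: SpectrumGrid, b: SpectrumGrid
) -> Tuple[SpectrumGrid, SpectrumGrid]:
    """Linearly interpolate both spectra onto their overlap range, at the
    finer of the two grid steps.  Identical grids pass through unchanged."""
    if a.same_grid(b):
        return a, b
    lo = max(a.wavelengths[0], b.wavelengths[0])
    hi = min(a.wavelengths[-1], b.wavelengths[-1])
    if lo >= hi:
        raise ValueError(
            f"wavelength ranges do not overlap: "
            f"[{a.wavelengths[0]}, {a.wavelengths[-1]}] vs "
            f"[{b.wavelengths[0]}, {b.wavelengths[-1]}]"
        )
    step = min(_median_step(a.wavelengths), _median_step(b.wavelengths))
    n = int(math.floor((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    out = []
    for s in (a, b):
        vals = np.interp(grid, s.wavelengths, s.delta_epsilon)
        out.append(SpectrumGrid(grid, vals, dict(s.metadata)))
    return out[0], out[1]


def first_derivative(spectrum: SpectrumGrid) -> DerivativeSpectrum:
    """d(d_eps)/d lambda via central differences (one-sided at the ends)."""
    if spectrum.wavelengths.size < 3:
        raise ValueError("need at least 3 grid points for a derivative")
    deriv = np.gradient(spectrum.delta_epsilon, spectrum.wavelengths)
    return DerivativeSpectrum(spectrum.wavelengths, deriv)


def extrema_positions(
    spectrum: SpectrumGrid, min_prominence: float = 0.05
) -> List[Tuple[float, float, int]]:
    """CD band extrema as (wavelength, value, sign) sorted by wavelength.

    Band extremes in the chiroptical sense: positive maxima (sign +1) and
    negative minima (sign -1); a positive-valued dip between two positive
    bands is not a band extremum.  Prominence threshold is
    ``min_prominence`` times max |d_eps|.  Returns an empty list for
    monotone curves.
    """
    v = spectrum.delta_epsilon
    scale = float(np.max(np.abs(v)))
    if scale == 0:
        return []
    prom = min_prominence * scale
    out: List[Tuple[float, float, int]] = []
    for sign, vals in ((+1, v), (-1, -v)):
        idx, _ = find_peaks(vals, prominence=prom)
        out.extend(
            (float(spectrum.wavelengths[i]), float(v[i]), sign)
            for i in idx
            if sign * v[i] > 0
        )
    out.sort(key=lambda t: t[0])
    return out


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(np.dot(a, b) / (na * nb))


def similarity_score(
    calc: SpectrumGrid, exp: SpectrumGrid, use_derivative: bool = False
) -> float:
    """Cosine similarity of two spectra on a common grid, in [-1, 1].

    With ``use_derivative`` the reported score is the mean of the curve
    cosine and the first-derivative cosine, capturing both the band pattern
    and the positions of rising/falling edges.
    """
    if not calc.same_grid(exp):
        raise ValueError("spectra must share a grid; resample first")
    score = _cosine(calc.delta_epsilon, exp.delta_epsilon)
    if use_derivative:
        d1 = first_derivative(calc).derivative
        d2 = first_derivative(exp).derivative
        score = 0.5 * (score + _cosine(d1, d2))
    return score


def match_extrema(
    calc: SpectrumGrid,
    exp: SpectrumGrid,
    tolerance_nm: float = 5.0,
    min_prominence: float = 0.05,
) -> int:
    """Count experimental extrema with a same-sign calculated extremum
    within ``tolerance_nm`` (each calculated extremum used at most once)."""
    ce = extrema_positions(calc, min_prominence)
    ee = extrema_positions(exp, min_prominence)
    used = [False] * len(ce)
    matched = 0
    for lam, _val, sign in ee:
        best, best_d = -1, tolerance_nm
        for j, (clam, _cval, csign) in enumerate(ce):
            if used[j] or csign != sign:
                continue
            d = abs(clam - lam)
            if d <= best_d:
                best, best_d = j, d
        if best >= 0:
            used[best] = True
            matched += 1
    return matched


def _clip(spectrum: SpectrumGrid, lo: float, hi: float) -> SpectrumGrid:
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 points inside comparison range [{lo}, {hi}]")
    return SpectrumGrid(
        spectrum.wavelengths[mask], spectrum.delta_epsilon[mask], dict(spectrum.metadata)
    )


def _normalize(
    spectrum: SpectrumGrid, window: Tuple[float, float]
) -> Tuple[Optional[SpectrumGrid], Optional[str]]:
    """Reference-band scaling with a flagged fallback.

    Tries the positive-reference-band scaling first; spectra lacking a
    positive band in the window are normalized by max |d_eps| instead and
    the deviation is reported as a flag (cosine scores are invariant to
    the choice, so the ranking is unaffected)."""
    try:
        return scale_spectrum(spectrum, window), None
    except ValueError as exc:
        peak = float(np.max(np.abs(spectrum.delta_epsilon)))
        if peak == 0:
            return None, f"zero spectrum: {exc}"
        return (
            spectrum.with_values(spectrum.delta_epsilon / peak, provenance="scaled"),
            f"reference-band scaling unavailable ({exc}); |max| normalization used",
        )


def assign_configuration(
    candidates: Sequence[Tuple[str, SpectrumGrid]],
    experimental: SpectrumGrid,
    mixture_pairs: Optional[Sequence[Tuple[str, str]]] = None,
    ratio_grid: Optional[Sequence[float]] = None,
    comparison_range: Tuple[float, float] = (195.0, 320.0),
    reference_window: Tuple[float, float] = (205.0, 230.0),
    extrema_tolerance_nm: float = 5.0,
) -> List[AssignmentResult]:
    """Rank candidate stereoisomers (and optional two-component mixtures)
    against an experimental spectrum.

    All spectra are clipped to ``comparison_range`` (further clipped to the
    data overlap), resampled onto the experimental grid, scaled to the
    positive reference band, and scored by the mean of curve and derivative
    cosine similarities.  Mixture candidates are generated for each pair in
    ``mixture_pairs`` over ``ratio_grid`` (default 0, 0.1, ..., 1, the ratio
    being the fraction of the first component).  Spectra without a positive
    band in ``reference_window`` are normalized by max |d_eps| instead and
    the result carries the flag in ``error``; only a genuinely zero
    spectrum is unscorable (ranked last with combined similarity -inf).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate spectra to rank")
    if ratio_grid is None:
        ratio_grid = [round(0.1 * k, 1) for k in range(11)]
    by_label: Dict[str, SpectrumGrid] = dict(candidates)
    if len(by_label) != len(candidates):
        raise ValueError("candidate labels must be unique")

    lo = max(comparison_range[0], experimental.wavelengths[0])
    hi = min(comparison_range[1], experimental.wavelengths[-1])
    for _lbl, s in candidates:
        lo = max(lo, s.wavelengths[0])
        hi = min(hi, s.wavelengths[-1])
    exp_clip = _clip(experimental, lo, hi)

    def prepare(label: str, spec: SpectrumGrid):
        cand_r, exp_r = resample_to_common_grid(_clip(spec, lo, hi), exp_clip)
        cand_s, cand_flag = _normalize(cand_r, reference_window)
        exp_s, exp_flag = _normalize(exp_r, reference_window)
        flags = []
        if cand_flag is not None:
            flags.append(f"{label}: {cand_flag}")
        if exp_flag is not None:
            flags.append(f"experimental: {exp_flag}")
        if cand_s is None or exp_s is None:
            return None, None, "; ".join(flags) or "normalization failed"
        return cand_s, exp_s, ("; ".join(flags) or None)

    entries: List[Tuple[str, Optional[float], Optional[SpectrumGrid]]] = [
        (label, None, spec) for label, spec in candidates
    ]
    if mixture_pairs:
        for la, lb in mixture_pairs:
            a, b = by_label[la], by_label[lb]
            ar, br = resample_to_common_grid(_clip(a, lo, hi), _clip(b, lo, hi))
            for ratio in ratio_grid:
                if ratio in (0.0, 1.0):
                    continue  # pure components already present
                mix = mixture_ecd([ar, br], [ratio, 1.0 - ratio])
                entries.append((f"{la}:{lb} {ratio:.0%}:{1-ratio:.0%}", float(ratio), mix))

    scored: List[AssignmentResult] = []
    for label, ratio, spec in entries:
        cand_s, exp_s, flag = prepare(label, spec)
        if cand_s is None:
            scored.append(AssignmentResult(label, float("nan"), float("nan"),
                                           -math.inf, 0, rank=-1,
                                           mixture_ratio=ratio, error=flag))
            continue
        curve = similarity_score(cand_s, exp_s)
        deriv = _cosine(first_derivative(cand_s).derivative,
                        first_derivative(exp_s).derivative)
        combined = 0.5 * (curve + deriv)
        n_match = match_extrema(cand_s, exp_s, extrema_tolerance_nm)
        scored.append(AssignmentResult(label, curve, deriv, combined, n_match,
                                       rank=-1, mixture_ratio=ratio, error=flag))

    # ties (e.g. enantiomer mixtures, which are shape-identical to their
    # dominant pure component after scaling) resolve toward the pure isomer
    scored.sort(
        key=lambda r: (
            -round(r.combined_similarity, 12) if math.isfinite(r.combined_similarity)
            else math.inf,
            r.mixture_ratio is not None,
            r.label,
        )
    )
    return [
        AssignmentResult(r.label, r.curve_similarity, r.derivative_similarity,
                         r.combined_similarity, r.extrema_matched,
                         rank=i + 1, mixture_ratio=r.mixture_ratio, error=r.error)
        for i, r in enumerate(scored)
    ]
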