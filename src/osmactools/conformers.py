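"""Conformer ensembles and Boltzmann statistical weights.

A conformer carries a relative Gibbs free energy (kcal/mol, referenced to
the most stable conformation) and a list of electronic transitions
(excitation energy plus rotatory strength) produced upstream by TDDFT.
The population of conformer *i* at temperature *T* is

    g_i = exp(-dG_i / RT) / sum_j exp(-dG_j / RT)

with R in kcal/(mol K).  Ensembles are truncated at a configurable dG
cutoff (default 4 kcal/mol) before spectral averaging.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EV_NM",
    "ElectronicTransition",
    "Conformer",
    "Ensemble",
    "WeightVector",
    "rereference_energies",
    "filter_by_delta_g",
    "boltzmann_weights",
    "read_ensemble_json",
    "write_ensemble_json",
]

#: Gas constant, kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98720e-3

#: Energy/wavelength conversion: E[eV] = EV_NM / lambda[nm].
EV_NM = 1239.841984


@dataclass(frozen=True)
class ElectronicTransition:
    """One electronic excitation: energy in eV and rotatory strength in
    1e-40 cgs units (signed; sets the sign and area of its ECD band)."""

    energy_ev: float
    rotatory_strength: float

    def __post_init__(self) -> None:
        if not self.energy_ev > 0:
            raise ValueError(f"transition energy must be positive, got {self.energy_ev}")

    @property
    def wavelength_nm(self) -> float:
        return EV_NM / self.energy_ev

    @classmethod
    def from_wavelength(cls, wavelength_nm: float, rotatory_strength: float) -> "ElectronicTransition":
        if not wavelength_nm > 0:
            raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
        return cls(EV_NM / wavelength_nm, rotatory_strength)


@dataclass(frozen=True)
class Conformer:
    id: str
    delta_g: float  # kcal/mol, relative to the most stable conformer
    transitions: Sequence[ElectronicTransition] = ()

    def negated(self) -> "Conformer":
        """Mirror-image conformer: every rotatory strength sign-flipped."""
        return replace(
            self,
            transitions=tuple(
                ElectronicTransition(t.energy_ev, -t.rotatory_strength)
                for t in self.transitions
            ),
        )


@dataclass(frozen=True)
class Ensemble:
    conformers: Sequence[Conformer]
    temperature: float = 298.15  # K
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.conformers) == 0:
            raise ValueError("ensemble must contain at least one conformer")
        object.__setattr__(self, "conformers", tuple(self.conformers))

    def delta_gs(self) -> List[float]:
        return [c.delta_g for c in self.conformers]


@dataclass(frozen=True)
class WeightVector:
    """Normalized Boltzmann populations keyed by conformer id."""

    weights: Dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"weights must sum to 1, got {total}")

    def as_list(self, ids: Sequence[str]) -> List[float]:
        return [self.weights[i] for i in ids]


def rereference_energies(ensemble: Ensemble) -> Ensemble:
    """Shift all conformer energies so the most stable one sits at dG = 0."""
    if not all(math.isfinite(c.delta_g) for c in ensemble.conformers):
        raise ValueError("conformer energies must be finite")
    g_min = min(c.delta_g for c in ensemble.conformers)
    return replace(
        ensemble,
        conformers=tuple(
            replace(c, delta_g=c.delta_g - g_min) for c in ensemble.conformers
        ),
    )


def filter_by_delta_g(ensemble: Ensemble, cutoff: float = 4.0) -> Ensemble:
    """Keep conformers with dG <= cutoff kcal/mol (inclusive).

    The ensemble must be re-referenced first so the most stable conformer
    (dG = 0) always survives.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")
    kept = tuple(c for c in ensemble.conformers if c.delta_g <= cutoff)
    return replace(ensemble, conformers=kept)


def boltzmann_weights(ensemble: Ensemble, temperature: "float | None" = None) -> WeightVector:
    """Boltzmann statistical weights of the conformers at ``temperature``.

    Defaults to the ensemble's own temperature (298.15 K unless set).
    """
    T = ensemble.temperature if temperature is None else temperature
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T}")
    gmin = min(c.delta_g for c in ensemble.conformers)
    # subtract the minimum before exponentiating for numerical stability;
    # the shift cancels in the normalization
    factors = [math.exp(-(c.delta_g - gmin) / (GAS_CONSTANT_KCAL * T)) for c in ensemble.conformers]
    total = sum(factors)
    return WeightVector({c.id: f / total for c, f in zip(ensemble.conformers, factors)})


# ---------------------------------------------------------------------------
# Ensemble file schema
#
# {
#   "temperature_K": 298.15,
#   "metadata": {"chirality": "R"},
#   "conformers": [
#     {"id": "conf-00", "delta_G_kcal_mol": 0.0,
#      "transitions": [{"wavelength_nm": 250.0, "rotatory_strength_1e-40cgs": 12.5},
#                      {"energy_eV": 5.2, "rotatory_strength_1e-40cgs": -3.0}]}
#   ]
# }
#
# Each transition gives either "wavelength_nm" or "energy_eV".


def _transition_from_record(rec: Dict[str, float]) -> ElectronicTransition:
    r = float(rec["rotatory_strength_1e-40cgs"])
    if "energy_eV" in rec:
        return ElectronicTransition(float(rec["energy_eV"]), r)
    if "wavelength_nm" in rec:
        return ElectronicTransition.from_wavelength(float(rec["wavelength_nm"]), r)
    raise ValueError("transition record needs 'energy_eV' or 'wavelength_nm'")


def read_ensemble_json(path: "str | Path") -> Ensemble:
    """Read a conformer ensemble from the JSON schema documented above."""
    data = json.loads(Path(path).read_text())
    conformers = [
        Conformer(
            id=str(rec.get("id", f"conf-{i:02d}")),
            delta_g=float(rec["delta_G_kcal_mol"]),
            transitions=tuple(_transition_from_record(t) for t in rec.get("transitions", [])),
        )
        for i, rec in enumerate(data["conformers"])
    ]
    return Ensemble(
        conformers=conformers,
        temperature=float(data.get("temperature_K", 298.15)),
        metadata=dict(data.get("metadata", {})),
    )


def write_ensemble_json(ensemble: Ensemble, path: "str | Path") -> None:
    data = {
        "temperature_K": ensemble.temperature,
        "metadata": dict(ensemble.metadata),
        "conformers": [
            {
                "id": c.id,
                "delta_G_kcal_mol": c.delta_g,
                "transitions": [
                    {
                        "energy_eV": t.energy_ev,
                        "rotatory_strength_1e-40cgs": t.rotatory_strength,
                    }
                    for t in c.transitions
                ],
            }
            for c in ensemble.conformers
        ],
    }
    Path(path).write_text(json.dumps(data, indent=1))
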