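"""Letter-coded component ledger and thermodynamic-cycle assembly.

Each leg of an ABFE calculation is a letter-coded component: restraint
attachment in the complex (a: protein conformational, l: ligand
conformational, t: ligand TR, or the merged m), ligand charge and
Lennard-Jones decoupling/recoupling (e, f, v, w — with SDR folding each
decouple/recouple pair into a single e or v), and restraint release
(b: analytic TR release, c: ligand conformational, r: protein
conformational, or the merged n, which folds the analytic b in).

Components are tabulated in the site→bulk (unbinding) direction, so

    ΔG°_bind = -Σ components,        Kd = C° · exp(ΔG°_bind / RT),

uncertainties combine in quadrature, and multiple non-interconverting poses
combine by a Boltzmann-weighted sum over the per-pose values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import T_DEFAULT, rt
from .estimators import FreeEnergyEstimate

#: Allowed estimation methods for each component letter.
LETTER_METHODS: dict[str, tuple[str, ...]] = {
    "m": ("MBAR",),
    "m*": ("MBAR",),
    "a": ("MBAR",),
    "l": ("MBAR",),
    "t": ("MBAR",),
    "e": ("MBAR", "TI-GQ"),
    "f": ("MBAR", "TI-GQ"),
    "v": ("MBAR", "TI-GQ"),
    "w": ("MBAR", "TI-GQ"),
    "n": ("MBAR",),
    "b": ("analytical",),
    "c": ("MBAR",),
    "r": ("MBAR",),
}

LETTER_DESCRIPTIONS: dict[str, str] = {
    "m": "attachment of all restraints (merged)",
    "m*": "attachment of ligand TR + conformational restraints (merged, no protein)",
    "a": "attachment of protein conformational restraints",
    "l": "attachment of ligand conformational restraints",
    "t": "attachment of ligand TR restraints",
    "e": "ligand charge decoupling in site (SDR: + recoupling in bulk)",
    "f": "ligand charge recoupling in bulk",
    "v": "ligand LJ decoupling in site (SDR: + recoupling in bulk)",
    "w": "ligand LJ recoupling in bulk",
    "n": "release of all restraints (merged, incl. analytic TR release)",
    "b": "analytic release of ligand TR restraints to 1 M",
    "c": "release of ligand conformational restraints",
    "r": "release of protein conformational restraints",
}

#: Letters each scheme requires. merged-style n folds the analytic b in, so
#: merged schemes do not list b separately; tevb and m*evbc add b explicitly.
SCHEME_LETTERS: dict[str, tuple[str, ...]] = {
    "split_ddm": ("a", "l", "t", "e", "f", "v", "w", "b", "c", "r"),
    "merged_sdr": ("m", "e", "v", "n"),
    "mevn": ("m", "e", "v", "n"),
    "tevb": ("t", "e", "v", "b"),
    "m_star_evbc": ("m*", "e", "v", "b", "c"),
}


@dataclass(frozen=True)
class Component:
    """One letter-coded free-energy contribution, in the site→bulk direction."""

    letter: str
    estimate: FreeEnergyEstimate
    system: str = "complex"   # complex | bulk ligand | apo protein | combined-box

    def __post_init__(self):
        if self.letter not in LETTER_METHODS:
            raise ValueError(f"unknown component letter {self.letter!r}")
        allowed = LETTER_METHODS[self.letter]
        if self.estimate.method not in allowed:
            raise ValueError(
                f"component {self.letter!r} must use one of {allowed}, "
                f"got {self.estimate.method!r}"
            )

    @property
    def value(self) -> float:
        return self.estimate.value

    @property
    def uncertainty(self) -> float:
        return self.estimate.uncertainty

    @property
    def description(self) -> str:
        return LETTER_DESCRIPTIONS[self.letter]


def component(letter: str, value: float, uncertainty: float = 0.0,
              method: str | None = None, system: str = "complex") -> Component:
    """Convenience constructor choosing a compatible default method."""
    if method is None:
        method = LETTER_METHODS[letter][0] if letter in LETTER_METHODS else "MBAR"
    return Component(letter=letter,
                     estimate=FreeEnergyEstimate(value=value, uncertainty=uncertainty,
                                                 method=method),
                     system=system)


@dataclass
class CycleResult:
    """Assembled binding free energy for one pose and scheme."""

    scheme: str
    components: dict[str, Component]
    dg_bind: float               # kcal/mol
    uncertainty: float           # kcal/mol, quadrature-combined
    kd: float                    # molar
    temperature: float = T_DEFAULT
    total_planned_time_ns: float | None = None

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "temperature": self.temperature,
            "components": {
                letter: {"value": c.value, "uncertainty": c.uncertainty,
                         "method": c.estimate.method, "system": c.system}
                for letter, c in self.components.items()
            },
            "dg_bind": self.dg_bind,
            "uncertainty": self.uncertainty,
            "kd_molar": self.kd,
            "total_planned_time_ns": self.total_planned_time_ns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CycleResult":
        comps = {
            letter: Component(
                letter=letter,
                estimate=FreeEnergyEstimate(value=e["value"], uncertainty=e["uncertainty"],
                                            method=e["method"]),
                system=e.get("system", "complex"),
            )
            for letter, e in d["components"].items()
        }
        return cls(scheme=d["scheme"], components=comps, dg_bind=d["dg_bind"],
                   uncertainty=d["uncertainty"], kd=d["kd_molar"],
                   temperature=d.get("temperature", T_DEFAULT),
                   total_planned_time_ns=d.get("total_planned_time_ns"))


class MissingComponentError(ValueError):
    """A scheme was assembled without one of its required letters."""


def kd_from_dg(dg_bind: float, temperature: float = T_DEFAULT, c0: float = 1.0) -> float:
    """Dissociation constant Kd = C°·exp(ΔG°_bind/RT), in molar."""
    return c0 * math.exp(dg_bind / rt(temperature))


def dg_from_kd(kd: float, temperature: float = T_DEFAULT, c0: float = 1.0) -> float:
    """Inverse of :func:`kd_from_dg`."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return rt(temperature) * math.log(kd / c0)


def assemble(
    components: Mapping[str, Component] | Sequence[Component],
    scheme: str,
    temperature: float = T_DEFAULT,
    total_planned_time_ns: float | None = None,
) -> CycleResult:
    """Assemble ΔG°_bind from a component ledger for the given scheme.

    Components must cover every letter the scheme requires (values in the
    site→bulk direction as tabulated: attach terms positive, release terms
    negative). ΔG°_bind is the negative component sum; the uncertainty is the
    root-sum-square of component uncertainties.
    """
    if scheme not in SCHEME_LETTERS:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEME_LETTERS)}")
    if not isinstance(components, Mapping):
        components = {c.letter: c for c in components}
    required = SCHEME_LETTERS[scheme]
    missing = [letter for letter in required if letter not in components]
    if missing:
        raise MissingComponentError(
            f"scheme {scheme!r} is missing component(s) {missing}"
        )
    used = {letter: components[letter] for letter in required}
    total = sum(c.value for c in used.values())
    unc = math.sqrt(sum(c.uncertainty ** 2 for c in used.values()))
    dg_bind = -total
    return CycleResult(
        scheme=scheme,
        components=used,
        dg_bind=dg_bind,
        uncertainty=unc,
        kd=kd_from_dg(dg_bind, temperature),
        temperature=temperature,
        total_planned_time_ns=total_planned_time_ns,
    )


# ---------------------------------------------------------------------------
# Merged-vs-split consistency
# ---------------------------------------------------------------------------

#: Merged letter -> the split letters whose sum it must equal.
CONSISTENCY_PAIRS: dict[str, tuple[str, ...]] = {
    "m": ("a", "l", "t"),
    "n": ("b", "c", "r"),
    "e": ("e", "f"),
    "v": ("v", "w"),
}


def _as_value_map(components) -> dict[str, float]:
    if isinstance(components, Mapping):
        return {k: (v.value if isinstance(v, Component) else float(v))
                for k, v in components.items()}
    return {c.letter: c.value for c in components}


def consistency_report(merged, split) -> dict[str, float]:
    """Absolute discrepancies between merged components and split sums.

    ``merged`` supplies values for (a subset of) m, e, v, n; ``split``
    supplies the individual split letters, or pre-summed entries keyed
    'a+l+t', 'e+f', 'v+w', 'b+c+r'. Returns the per-pair discrepancies plus
    their maximum under the key 'max'.
    """
    merged_v = _as_value_map(merged)
    split_v = _as_value_map(split)
    report: dict[str, float] = {}
    for m_letter, s_letters in CONSISTENCY_PAIRS.items():
        if m_letter not in merged_v:
            continue
        summed_key = "+".join(s_letters)
        if summed_key in split_v:
            split_sum = split_v[summed_key]
        elif all(s in split_v for s in s_letters):
            split_sum = sum(split_v[s] for s in s_letters)
        else:
            continue
        report[f"{m_letter} vs {summed_key}"] = abs(merged_v[m_letter] - split_sum)
    if not report:
        raise ValueError("no comparable merged/split component pairs supplied")
    report["max"] = max(report.values())
    return report


def consistency_report_poses(per_pose: Mapping[str, tuple]) -> dict[str, float]:
    """Merged-vs-split discrepancies across poses: {pose: (merged, split)}.

    Pose labels must match between the merged and split ledgers (they are the
    mapping keys, so mismatches surface as missing entries). Returns per-pose
    per-pair discrepancies plus the overall 'max'.
    """
    out: dict[str, float] = {}
    overall = 0.0
    for pose, (merged, split) in per_pose.items():
        rep = consistency_report(merged, split)
        overall = max(overall, rep.pop("max"))
        for key, value in rep.items():
            out[f"{pose}: {key}"] = value
    out["max"] = overall
    return out


# ---------------------------------------------------------------------------
# Multi-pose combination
# ---------------------------------------------------------------------------

def combine_poses(dg_values: Sequence[float], temperature: float = T_DEFAULT) -> float:
    """Boltzmann combination of per-pose binding free energies.

    ΔG°_bind = -RT ln Σ_i exp(-ΔG°_i/RT), computed with an overflow-safe
    log-sum-exp. Assumes the poses do not interconvert during their
    individual calculations; the lowest ΔG°_i dominates the sum.
    """
    dg = np.asarray(dg_values, dtype=float)
    if dg.size == 0:
        raise ValueError("combine_poses requires at least one pose")
    RT = rt(temperature)
    return float(-RT * logsumexp(-dg / RT))


def write_result_json(result: CycleResult, path) -> None:
    from pathlib import Path
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_result_json(path) -> CycleResult:
    from pathlib import Path
    return CycleResult.from_dict(json.loads(Path(path).read_text()))
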