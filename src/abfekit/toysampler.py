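"""Synthetic-data generation: toy potentials, Metropolis sampling, fixtures.

Molecular dynamics is replaced by Metropolis Monte Carlo on low-dimensional
toy potentials with closed-form free energies, which makes every other
module testable at desk scale: window tables with known ΔG for the
estimators, a six-coordinate restraint field with an analytically solvable
binding cycle for the cycle bookkeeping, and small protein–ligand PDB
fixtures for anchor selection and restraint construction.

All sampling is deterministic given a seed: one explicit RNG stream per
operation, identical seed + parameters → bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .anchors import AnchorSet, SearchZone
from .constants import ORIENTATIONAL_VOLUME, T_DEFAULT, V0_STANDARD, rt
from .cycle import Component, CycleResult, assemble
from .estimators import (FreeEnergyEstimate, LambdaSchedule, WindowEnergyTable,
                         mbar, mbar_block_uncertainty)
from .restraints import TRRestraint
from .standardstate import tr_release_free_energy
from .structio import Atom, Structure, assign_roles


class AcceptanceError(RuntimeError):
    """Metropolis acceptance collapsed below 0.01 despite step tuning."""


# ---------------------------------------------------------------------------
# Toy potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicLadder:
    """1-D harmonic well whose spring constant interpolates geometrically.

    k(λ) = k0 · (k1/k0)^λ, centre fixed. The free-energy difference between
    any two λ values is analytic: ΔG = (RT/2)(λb − λa) ln(k1/k0), and
    <∂U/∂λ> is constant in λ, so Gaussian quadrature of any order is exact.
    """

    k0: float
    k1: float
    center: float = 0.0

    def __post_init__(self):
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("spring constants must be positive")

    ndim = 1
    form = "harmonic_ladder"
    default_stride = 5

    def k_of(self, lam: float) -> float:
        return self.k0 * (self.k1 / self.k0) ** lam

    def reduced_energy(self, x: np.ndarray, lam: float, temperature: float) -> np.ndarray:
        dx = x[:, 0] - self.center
        return 0.5 * self.k_of(lam) * dx * dx / rt(temperature)

    def dudl(self, x: np.ndarray, lam: float) -> np.ndarray:
        dx = x[:, 0] - self.center
        return 0.5 * self.k_of(lam) * math.log(self.k1 / self.k0) * dx * dx

    def analytic_dg(self, lam_a: float, lam_b: float, temperature: float = T_DEFAULT) -> float:
        return 0.5 * rt(temperature) * (lam_b - lam_a) * math.log(self.k1 / self.k0)

    def initial_state(self, lam: float, rng: np.random.Generator) -> np.ndarray:
        return np.array([self.center])

    def initial_step(self, lam: float, temperature: float) -> np.ndarray:
        return np.array([math.sqrt(rt(temperature) / self.k_of(lam))])

    def compile_scalar(self, lam: float, temperature: float):
        half_k = 0.5 * self.k_of(lam) / rt(temperature)
        center = self.center

        def log_target(x: tuple) -> float:
            dx = x[0] - center
            return -half_k * dx * dx

        return log_target


@dataclass(frozen=True)
class LambdaCoupled:
    """1-D base well plus a λ-coupled perturbation: U = ½k0 x² + λ^p · ½c x².

    Z(λ) = sqrt(2πRT/(k0 + λ^p c)) gives the analytic ΔG; the derivative
    <∂U/∂λ> = p λ^(p-1) · ½c <x²> is analytic too, which makes this the
    reference potential for finite-difference ∂U/∂λ checks.
    """

    k0: float
    c: float
    exponent: float = 1.0

    def __post_init__(self):
        if self.k0 <= 0:
            raise ValueError("base spring constant must be positive")
        if self.k0 + min(0.0, self.c) <= 0:
            raise ValueError("total spring constant must stay positive on [0, 1]")

    ndim = 1
    form = "lambda_coupled"
    default_stride = 5

    def k_total(self, lam: float) -> float:
        return self.k0 + lam ** self.exponent * self.c

    def reduced_energy(self, x: np.ndarray, lam: float, temperature: float) -> np.ndarray:
        return 0.5 * self.k_total(lam) * x[:, 0] ** 2 / rt(temperature)

    def dudl(self, x: np.ndarray, lam: float) -> np.ndarray:
        if lam == 0 and self.exponent < 1:
            raise ValueError("dU/dλ singular at λ=0 for exponent < 1")
        return self.exponent * lam ** (self.exponent - 1.0) * 0.5 * self.c * x[:, 0] ** 2

    def analytic_dg(self, lam_a: float, lam_b: float, temperature: float = T_DEFAULT) -> float:
        return 0.5 * rt(temperature) * math.log(self.k_total(lam_b) / self.k_total(lam_a))

    def analytic_dudl_mean(self, lam: float, temperature: float = T_DEFAULT) -> float:
        return (self.exponent * lam ** (self.exponent - 1.0)
                * 0.5 * self.c * rt(temperature) / self.k_total(lam))

    def initial_state(self, lam: float, rng: np.random.Generator) -> np.ndarray:
        return np.zeros(1)

    def initial_step(self, lam: float, temperature: float) -> np.ndarray:
        return np.array([math.sqrt(rt(temperature) / self.k_total(lam))])

    def compile_scalar(self, lam: float, temperature: float):
        half_k = 0.5 * self.k_total(lam) / rt(temperature)

        def log_target(x: tuple) -> float:
            return -half_k * x[0] * x[0]

        return log_target


@dataclass(frozen=True)
class TRField:
    """Six-coordinate restraint field: λ-scalable harmonic terms with Jacobian.

    State vector is (r, θ, Θ, φ, Φ, Ψ) in Å and radians. Each term is a
    :class:`~abfekit.restraints.TRRestraint` parameter set with a well depth
    and a λ-scaling function; the sampling measure carries the Jacobian
    r² sinθ sinΘ. This is the desk-scale surrogate for the bound complex:
    "site interactions" and the TR restraint are both terms of this form.
    """

    terms: tuple[tuple[TRRestraint, float, Callable[[float], float]], ...]
    r_bounds: tuple[float, float]

    ndim = 6
    form = "tr_restraint_field"
    default_stride = 10

    def __post_init__(self):
        lo, hi = self.r_bounds
        if not 0 <= lo < hi:
            raise ValueError("invalid radial bounds")

    def _term_energy(self, x: np.ndarray, tr: TRRestraint) -> np.ndarray:
        refs = np.array([tr.r0] + [math.radians(v) for v in tr.references[1:]])
        ks = np.asarray(tr.force_constants)
        delta = x - refs
        # wrap the three dihedral differences to (-π, π]
        delta[:, 3:] = np.pi - np.mod(np.pi - delta[:, 3:], 2.0 * np.pi)
        return 0.5 * (ks * delta * delta).sum(axis=1)

    def reduced_energy(self, x: np.ndarray, lam: float, temperature: float) -> np.ndarray:
        RT = rt(temperature)
        u = np.zeros(x.shape[0])
        for tr, depth, scale in self.terms:
            u += scale(lam) * (self._term_energy(x, tr) - depth)
        return u / RT

    def log_measure(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return (2.0 * np.log(x[:, 0]) + np.log(np.sin(x[:, 1]))
                    + np.log(np.sin(x[:, 2])))

    def in_domain(self, x: np.ndarray) -> np.ndarray:
        lo, hi = self.r_bounds
        ok = (x[:, 0] > lo) & (x[:, 0] < hi)
        ok &= (x[:, 1] > 0) & (x[:, 1] < math.pi)
        ok &= (x[:, 2] > 0) & (x[:, 2] < math.pi)
        return ok

    def wrap(self, x: np.ndarray) -> np.ndarray:
        x = x.copy()
        x[:, 3:] = np.pi - np.mod(np.pi - x[:, 3:], 2.0 * np.pi)
        return x

    def flat_log_volume(self) -> float:
        """ln ∫ J dx over the domain (the λ=0 reference measure)."""
        lo, hi = self.r_bounds
        return math.log((hi ** 3 - lo ** 3) / 3.0) + 2.0 * math.log(2.0) + 3.0 * math.log(2.0 * math.pi)

    def initial_state(self, lam: float, rng: np.random.Generator) -> np.ndarray:
        tr = self.terms[0][0]
        return np.array([tr.r0, math.radians(tr.theta0), math.radians(tr.Theta0),
                         math.radians(tr.phi0), math.radians(tr.Phi0), math.radians(tr.Psi0)])

    def initial_step(self, lam: float, temperature: float) -> np.ndarray:
        return np.array([0.3, 0.15, 0.15, 0.3, 0.3, 0.3])

    def wrap_scalar(self, x: tuple) -> tuple:
        pi, two_pi = math.pi, 2.0 * math.pi
        return (x[0], x[1], x[2],
                (x[3] + pi) % two_pi - pi,
                (x[4] + pi) % two_pi - pi,
                (x[5] + pi) % two_pi - pi)

    def compile_scalar(self, lam: float, temperature: float):
        """Precompiled scalar log-target (reduced energy + Jacobian, domain-aware)."""
        RT = rt(temperature)
        const = 0.0
        terms = []
        for tr, depth, scale in self.terms:
            s = scale(lam)
            const += s * depth / RT
            if s == 0.0:
                continue
            refs = (tr.r0, math.radians(tr.theta0), math.radians(tr.Theta0),
                    math.radians(tr.phi0), math.radians(tr.Phi0), math.radians(tr.Psi0))
            ks = tuple(0.5 * s * k / RT for k in tr.force_constants)
            terms.append((ks, refs))
        lo, hi = self.r_bounds
        pi, two_pi = math.pi, 2.0 * math.pi
        log, sin = math.log, math.sin

        def log_target(x: tuple) -> float | None:
            r, th, Th = x[0], x[1], x[2]
            if not (lo < r < hi and 0.0 < th < pi and 0.0 < Th < pi):
                return None
            e = -const
            for ks, refs in terms:
                d = r - refs[0]
                e += ks[0] * d * d
                d = th - refs[1]
                e += ks[1] * d * d
                d = Th - refs[2]
                e += ks[2] * d * d
                for j in (3, 4, 5):
                    dd = (x[j] - refs[j] + pi) % two_pi - pi
                    e += ks[j] * dd * dd
            return -e + 2.0 * log(r) + log(sin(th)) + log(sin(Th))

        return log_target


ToyPotential = HarmonicLadder | LambdaCoupled | TRField


# ---------------------------------------------------------------------------
# Metropolis sampling
# ---------------------------------------------------------------------------

def _metropolis_chain(
    potential,
    lam: float,
    n_samples: int,
    rng: np.random.Generator,
    temperature: float,
    stride: int = 1,
) -> np.ndarray:
    """One tuned Metropolis chain; returns (n_samples, ndim) thinned states."""
    x = tuple(float(v) for v in potential.initial_state(lam, rng))
    step = potential.initial_step(lam, temperature).astype(float)
    ndim = len(x)

    if hasattr(potential, "compile_scalar"):
        log_target = potential.compile_scalar(lam, temperature)
    else:
        has_measure = hasattr(potential, "log_measure")

        def log_target(state: tuple) -> float | None:
            arr = np.asarray(state)[None, :]
            if hasattr(potential, "in_domain") and not bool(potential.in_domain(arr)[0]):
                return None
            lt = -float(potential.reduced_energy(arr, lam, temperature)[0])
            if has_measure:
                lt += float(potential.log_measure(arr)[0])
            return lt

    wrap_scalar = getattr(potential, "wrap_scalar", None)

    def run(n: int, current: tuple, current_lt: float, step: np.ndarray,
            keep_stride: int = 1):
        accepted = 0
        n_keep = n // keep_stride
        states = np.empty((n_keep, ndim))
        kept = 0
        increments = rng.standard_normal((n, ndim)) * step
        log_us = np.log(rng.random(n))
        for i in range(n):
            inc = increments[i]
            proposal = tuple(current[j] + inc[j] for j in range(ndim))
            if wrap_scalar is not None:
                proposal = wrap_scalar(proposal)
            lt = log_target(proposal)
            if lt is not None and log_us[i] < lt - current_lt:
                current, current_lt = proposal, lt
                accepted += 1
            if (i + 1) % keep_stride == 0 and kept < n_keep:
                states[kept] = current
                kept += 1
        return states[:kept], current, current_lt, accepted / max(n, 1)

    current_lt = log_target(x)
    if current_lt is None:
        raise ValueError("initial state outside the sampling domain")
    # Step-size tuning: short pilot runs until acceptance >= 0.2 (cap growth).
    acc = 0.0
    for _ in range(12):
        _, x, current_lt, acc = run(200, x, current_lt, step)
        if 0.2 <= acc <= 0.65:
            break
        step = step * (0.5 if acc < 0.2 else 1.8)
    if acc < 0.01:
        raise AcceptanceError(
            f"Metropolis acceptance {acc:.3f} < 0.01 at λ={lam}; adjust step sizes"
        )
    burn = max(10, (n_samples * stride) // 10)
    _, x, current_lt, _ = run(burn, x, current_lt, step)
    states, _, _, acc = run(n_samples * stride, x, current_lt, step, keep_stride=stride)
    if acc < 0.01:
        raise AcceptanceError(
            f"Metropolis acceptance {acc:.3f} < 0.01 at λ={lam}; adjust step sizes"
        )
    if states.shape[0] != n_samples:  # defensive: stride bookkeeping must be exact
        raise RuntimeError("thinned chain length mismatch")
    return states


def sample_windows(
    potential,
    schedule: LambdaSchedule,
    n_samples: int,
    seed: int,
    temperature: float = T_DEFAULT,
    stride: int | None = None,
) -> WindowEnergyTable:
    """Metropolis-sample every window and cross-evaluate reduced potentials.

    One chain per window (burn-in 10%, step sizes tuned to ≥0.2 acceptance,
    thinning stride keeps every ``stride``-th step to decorrelate samples);
    u_kn is filled by re-evaluating every sample in every window. Per-window
    ∂U/∂λ samples are attached when the potential defines them.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples per window")
    if stride is None:
        stride = getattr(potential, "default_stride", 1)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rng = np.random.default_rng(seed)
    lambdas = schedule.lambdas
    all_states = [
        _metropolis_chain(potential, lam, n_samples, rng, temperature, stride)
        for lam in lambdas
    ]
    X = np.vstack(all_states)
    u_kn = np.vstack([potential.reduced_energy(X, lam, temperature) for lam in lambdas])
    dudl_k = None
    if hasattr(potential, "dudl"):
        try:
            dudl_k = [potential.dudl(states, lam)
                      for states, lam in zip(all_states, lambdas)]
        except ValueError:
            dudl_k = None
    return WindowEnergyTable(
        u_kn=u_kn,
        N_k=np.full(len(lambdas), n_samples),
        schedule=schedule,
        dudl_k=dudl_k,
        temperature=temperature,
    )


def exact_gaussian_windows(
    spring_constants: Sequence[float],
    centers: Sequence[float] | None,
    n_samples: int,
    seed: int,
    temperature: float = T_DEFAULT,
) -> WindowEnergyTable:
    """Window table with samples drawn exactly from 1-D harmonic wells.

    Window k has reduced potential ½ k_k (x − c_k)² / RT; samples are exact
    Gaussians, so estimator checks are free of Monte-Carlo autocorrelation.
    """
    ks = np.asarray(spring_constants, dtype=float)
    cs = np.zeros_like(ks) if centers is None else np.asarray(centers, dtype=float)
    if np.any(ks <= 0):
        raise ValueError("spring constants must be positive")
    rng = np.random.default_rng(seed)
    RT = rt(temperature)
    samples = [cs[k] + math.sqrt(RT / ks[k]) * rng.standard_normal(n_samples)
               for k in range(ks.size)]
    x = np.concatenate(samples)
    u_kn = np.vstack([0.5 * ks[k] * (x - cs[k]) ** 2 / RT for k in range(ks.size)])
    return WindowEnergyTable(u_kn=u_kn, N_k=np.full(ks.size, n_samples),
                             temperature=temperature)


# ---------------------------------------------------------------------------
# Toy protein–ligand fixture
# ---------------------------------------------------------------------------

_RESIDUE_TEMPLATE = {
    "N": np.array([-0.57, 1.36, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.52, 0.00, 0.00]),
    "O": np.array([2.15, 1.06, 0.00]),
}


def make_toy_complex(seed: int = 0) -> Structure:
    """A 3-residue helical peptide fragment plus a branched toy ligand.

    The peptide supplies valid protein backbone anchor candidates; the
    ligand (8–15 heavy carbons, randomized tree topology with 1.5 Å bonds
    and CONECT connectivity) sits in a pocket-like position so a search zone
    at its centroid with radius 4 Å is always non-empty.
    """
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 0
    # helical peptide: ~100° twist and 1.5 Å rise per residue
    for i in range(3):
        twist = math.radians(100.0 * i)
        rot = np.array([[math.cos(twist), -math.sin(twist), 0.0],
                        [math.sin(twist), math.cos(twist), 0.0],
                        [0.0, 0.0, 1.0]])
        shift = np.array([2.3 * math.cos(twist), 2.3 * math.sin(twist), 1.5 * i])
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(Atom(serial=serial, name=name,
                              element="N" if name == "N" else ("O" if name == "O" else "C"),
                              residue_name="ALA", residue_number=i + 1, chain_id="A",
                              position=rot @ _RESIDUE_TEMPLATE[name] + shift))
    # branched ligand: random tree, bond length 1.5 Å, max degree 3
    n_heavy = int(rng.integers(8, 16))
    lig_local = [np.zeros(3)]
    parents: list[tuple[int, int]] = []
    degree = [0]
    while len(lig_local) < n_heavy:
        candidates = [i for i, d in enumerate(degree) if d < 3]
        parent = int(rng.choice(candidates))
        for _ in range(50):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = lig_local[parent] + 1.5 * direction
            if all(np.linalg.norm(pos - q) >= 1.2 for q in lig_local):
                break
        else:
            continue
        lig_local.append(pos)
        parents.append((parent, len(lig_local) - 1))
        degree[parent] += 1
        degree.append(1)
    lig_center = np.array([6.5, 2.0, 1.5])  # pocket-like offset from the peptide
    offset = lig_center - np.mean(lig_local, axis=0)
    first_lig_serial = serial + 1
    for i, pos in enumerate(lig_local):
        serial += 1
        atoms.append(Atom(serial=serial, name=f"C{i + 1}", element="C",
                          residue_name="LIG", residue_number=1, chain_id="B",
                          position=pos + offset))
    bonds = {(first_lig_serial + a, first_lig_serial + b) for a, b in parents}
    structure = Structure(atoms=atoms, bonds=bonds)
    assign_roles(structure, role_hints={"LIG": "ligand"})
    return structure


def default_toy_zone(structure: Structure, radius: float = 4.0) -> SearchZone:
    """Search zone at the ligand heavy-atom centroid."""
    lig = structure.positions([a.serial for a in structure.ligand_atoms(heavy_only=True)])
    return SearchZone(center=lig.mean(axis=0), radius=radius)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle for the analytic TR release
# ---------------------------------------------------------------------------

_DUMMY_ANCHORS = AnchorSet(P1=1, P2=2, P3=3, L1=4, L2=5, L3=6,
                           zone=SearchZone(center=np.zeros(3), radius=1.0))

_RELEASE_LADDER = (0.0, 0.002, 0.01, 0.04, 0.12, 0.35, 1.0)


def mc_release_oracle(
    tr: TRRestraint,
    temperature: float = T_DEFAULT,
    n_steps: int = 4000,
    seed: int = 0,
    n_blocks: int = 5,
) -> FreeEnergyEstimate:
    """Monte-Carlo estimate of the analytic TR release free energy.

    Metropolis chains sample the six restraint coordinates (with their
    Jacobian) along a λ ladder that scales the restraint from zero to full
    strength; MBAR connects the restrained state to the flat
    Jacobian-weighted reference whose volume is known in closed form, and
    the release free energy to the 1 M standard state follows. Uncertainty
    is block analysis over the MBAR end-to-end ΔG.
    """
    RT = rt(temperature)
    sigma_r = math.sqrt(RT / tr.k_r)
    r_lo = max(0.0, tr.r0 - 10.0 * sigma_r)
    r_hi = tr.r0 + 10.0 * sigma_r
    field = TRField(terms=((tr, 0.0, lambda lam: lam),), r_bounds=(r_lo, r_hi))
    schedule = LambdaSchedule(mode="explicit", lambdas=_RELEASE_LADDER)
    table = sample_windows(field, schedule, n_steps, seed, temperature)
    result = mbar(table)
    delta_f = result.delta_f(0, -1)           # ln(Z_flat / Z_TR)
    log_z_flat = field.flat_log_volume()
    log_ratio = math.log(ORIENTATIONAL_VOLUME * V0_STANDARD) - log_z_flat + delta_f
    dg = -RT * log_ratio
    se = mbar_block_uncertainty(table, n_blocks)
    return FreeEnergyEstimate(value=dg, uncertainty=se, method="MBAR")


# ---------------------------------------------------------------------------
# End-to-end toy binding cycles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyCycleModel:
    """A six-coordinate toy binding model with an analytic ΔG°_bind.

    The bound state is a harmonic "site well" of total depth ε split into an
    electrostatic-like part and a Lennard-Jones-like part; the TR restraint
    is a separate harmonic term. Site wells and restraint share reference
    coordinates, and the analytic binding free energy is
    -(ΔG_TR-release(site) + ε) with the site treated as a restraint-like
    integral.
    """

    restraint: TRRestraint
    site_elec: TRRestraint
    site_lj: TRRestraint
    depth_elec: float
    depth_lj: float
    temperature: float = T_DEFAULT

    @property
    def site_combined(self) -> TRRestraint:
        ks_e = self.site_elec.force_constants
        ks_v = self.site_lj.force_constants
        combined = [a + b for a, b in zip(ks_e, ks_v)]
        return TRRestraint(self.restraint.anchors, *self.restraint.references, *combined)

    def analytic_dg_bind(self) -> float:
        release_site = tr_release_free_energy(self.site_combined, self.temperature,
                                              method="quadrature")
        return -(release_site + self.depth_elec + self.depth_lj)

    def r_bounds(self) -> tuple[float, float]:
        RT = rt(self.temperature)
        k_min = min(self.restraint.k_r, self.site_combined.k_r)
        sigma = math.sqrt(RT / k_min)
        return (max(0.0, self.restraint.r0 - 10.0 * sigma), self.restraint.r0 + 10.0 * sigma)


def default_toy_cycle_model(temperature: float = T_DEFAULT) -> ToyCycleModel:
    refs = (5.0, 90.0, 90.0, 0.0, 0.0, 0.0)
    restraint = TRRestraint(_DUMMY_ANCHORS, *refs,
                            k_r=10.0, k_theta=100.0, k_Theta=100.0,
                            k_phi=100.0, k_Phi=100.0, k_Psi=100.0)
    site_elec = TRRestraint(_DUMMY_ANCHORS, *refs,
                            k_r=6.0, k_theta=60.0, k_Theta=60.0,
                            k_phi=60.0, k_Phi=60.0, k_Psi=60.0)
    site_lj = TRRestraint(_DUMMY_ANCHORS, *refs,
                          k_r=14.0, k_theta=140.0, k_Theta=140.0,
                          k_phi=140.0, k_Phi=140.0, k_Psi=140.0)
    return ToyCycleModel(restraint=restraint, site_elec=site_elec, site_lj=site_lj,
                         depth_elec=5.0, depth_lj=13.0, temperature=temperature)


_ATTACH_LADDER = (0.0, 0.05, 0.15, 0.3, 0.5, 0.75, 1.0)


def _leg_estimate(field: TRField, n_samples: int, seed: int,
                  temperature: float, n_blocks: int) -> FreeEnergyEstimate:
    schedule = LambdaSchedule(mode="explicit", lambdas=_ATTACH_LADDER)
    table = sample_windows(field, schedule, n_samples, seed, temperature)
    result = mbar(table)
    return FreeEnergyEstimate(value=result.delta_g(0, -1),
                              uncertainty=mbar_block_uncertainty(table, n_blocks),
                              method="MBAR", blocks=n_blocks)


def toy_cycle_components(
    model: ToyCycleModel,
    scheme: str = "merged_sdr",
    n_samples: int = 1500,
    seed: int = 1,
    n_blocks: int = 5,
) -> dict[str, Component]:
    """Sampled letter-coded components of the toy binding cycle.

    merged_sdr: m attaches the restraint in the bound state, e and v remove
    the electrostatic-like and LJ-like site wells with the restraint on, and
    n is the analytic TR release. split_ddm computes the same legs as t/e/v
    with f = w = 0 (the toy bulk is structureless, so there is nothing to
    recouple) and a = l = c = r = 0 (no conformational restraints in the
    toy); b is the analytic release.
    """
    T = model.temperature
    bounds = model.r_bounds()
    on = lambda lam: 1.0
    up = lambda lam: lam
    down = lambda lam: 1.0 - lam

    attach_field = TRField(terms=(
        (model.site_elec, model.depth_elec, on),
        (model.site_lj, model.depth_lj, on),
        (model.restraint, 0.0, up),
    ), r_bounds=bounds)
    elec_field = TRField(terms=(
        (model.site_elec, model.depth_elec, down),
        (model.site_lj, model.depth_lj, on),
        (model.restraint, 0.0, on),
    ), r_bounds=bounds)
    lj_field = TRField(terms=(
        (model.site_lj, model.depth_lj, down),
        (model.restraint, 0.0, on),
    ), r_bounds=bounds)

    rng = np.random.default_rng(seed)
    leg_seeds = rng.integers(0, 2**31 - 1, size=3)
    attach = _leg_estimate(attach_field, n_samples, int(leg_seeds[0]), T, n_blocks)
    elec = _leg_estimate(elec_field, n_samples, int(leg_seeds[1]), T, n_blocks)
    lj = _leg_estimate(lj_field, n_samples, int(leg_seeds[2]), T, n_blocks)
    release = tr_release_free_energy(model.restraint, T, method="quadrature")

    if scheme in ("merged_sdr", "mevn"):
        return {
            "m": Component("m", attach),
            "e": Component("e", elec, system="combined-box"),
            "v": Component("v", lj, system="combined-box"),
            "n": Component("n", FreeEnergyEstimate(release, 0.0, "MBAR"),
                           system="bulk ligand"),
        }
    if scheme == "split_ddm":
        zero = lambda: FreeEnergyEstimate(0.0, 0.0, "MBAR")
        return {
            "a": Component("a", zero()),
            "l": Component("l", zero()),
            "t": Component("t", attach),
            "e": Component("e", elec),
            "f": Component("f", zero(), system="bulk ligand"),
            "v": Component("v", lj),
            "w": Component("w", zero(), system="bulk ligand"),
            "b": Component("b", FreeEnergyEstimate(release, 0.0, "analytical"),
                           system="bulk ligand"),
            "c": Component("c", zero(), system="bulk ligand"),
            "r": Component("r", zero(), system="apo protein"),
        }
    raise ValueError(f"toy cycle supports merged_sdr/mevn/split_ddm, not {scheme!r}")


def toy_cycle(
    scheme: str = "merged_sdr",
    seed: int = 1,
    n_samples: int = 1500,
    temperature: float = T_DEFAULT,
) -> tuple[CycleResult, float]:
    """Run a full toy binding cycle; returns (assembled result, analytic ΔG°_bind)."""
    model = default_toy_cycle_model(temperature)
    comps = toy_cycle_components(model, scheme, n_samples=n_samples, seed=seed)
    return assemble(comps, scheme, temperature), model.analytic_dg_bind()
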