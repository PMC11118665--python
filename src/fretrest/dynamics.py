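"""Coarse-grained restrained Langevin dynamics and restraint-file export.

This engine is a deliberate physics substitution: instead of explicit-solvent
all-atom MD, the baseline potential is the initial structure's Cα elastic
network, which keeps the starting conformation metastable, and harmonic
distance restraints (rest lengths from the target structure) supply the
driving force.  The integrator is overdamped (Brownian) Langevin dynamics, so
replicate runs differ only through independent noise streams.

Units: coordinates in Å, energies in kJ mol⁻¹, time in ps, temperatures in K.
Stiffnesses are accepted in the MD-community convention kJ mol⁻¹ nm⁻² and
converted internally to Å⁻².  The friction (drag) coefficient is in
kJ mol⁻¹ ps Å⁻².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .enm import build_enm
from .selection import ResiduePair
from .structures import Ensemble, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "KB",
    "RestraintTerm",
    "EngineParams",
    "Trajectory",
    "restraint_energy",
    "build_restraints",
    "run_dynamics",
    "replicate_runs",
    "make_engine",
    "export_restraints",
    "read_restraints_tsv",
]

#: Boltzmann constant, kJ mol⁻¹ K⁻¹
KB = 0.008314463

_NM2_TO_A2 = 0.01  # kJ/mol/nm² -> kJ/mol/Å²


def _integrate_chunk_numpy(x, i_idx, j_idx, k_arr, r0_arr, dt_over_gamma, noise):
    n = len(x)
    for s in range(noise.shape[0]):
        d = x[i_idx] - x[j_idx]
        dist = np.sqrt(np.einsum("ij,ij->i", d, d))
        coef = -k_arr * (dist - r0_arr) / dist
        f_pair = coef[:, None] * d
        force = np.empty_like(x)
        for c in range(3):
            force[:, c] = np.bincount(i_idx, f_pair[:, c], minlength=n) - np.bincount(
                j_idx, f_pair[:, c], minlength=n
            )
        x = x + force * dt_over_gamma + noise[s]
    return x


try:  # jitted inner loop; the numpy path is the reference implementation
    import numba

    @numba.njit(cache=True)
    def _integrate_chunk_jit(x, i_idx, j_idx, k_arr, r0_arr, dt_over_gamma, noise):
        n = x.shape[0]
        m = i_idx.shape[0]
        x = x.copy()
        for s in range(noise.shape[0]):
            force = np.zeros((n, 3))
            for p in range(m):
                a, b = i_idx[p], j_idx[p]
                dx = x[a, 0] - x[b, 0]
                dy = x[a, 1] - x[b, 1]
                dz = x[a, 2] - x[b, 2]
                dist = np.sqrt(dx * dx + dy * dy + dz * dz)
                c = -k_arr[p] * (dist - r0_arr[p]) / dist
                force[a, 0] += c * dx
                force[a, 1] += c * dy
                force[a, 2] += c * dz
                force[b, 0] -= c * dx
                force[b, 1] -= c * dy
                force[b, 2] -= c * dz
            for q in range(n):
                for c3 in range(3):
                    x[q, c3] += force[q, c3] * dt_over_gamma + noise[s, q, c3]
        return x

    _integrate_chunk = _integrate_chunk_jit
except ImportError:  # pragma: no cover
    _integrate_chunk = _integrate_chunk_numpy


@dataclass(frozen=True)
class RestraintTerm:
    """Harmonic restraint (k_r/2)(R - R⁰)² on one Cα–Cα separation."""

    pair: ResiduePair
    target_distance: float  # Å
    stiffness: float = 5000.0  # kJ mol⁻¹ nm⁻²

    def __post_init__(self):
        if self.target_distance <= 0:
            raise ValueError("target_distance must be > 0")
        if self.stiffness < 0:
            raise ValueError("stiffness must be >= 0")


@dataclass
class EngineParams:
    """Parameters of the coarse-grained Langevin engine.

    ``friction`` is the drag per bead; single-spring relaxation times are
    friction/stiffness (sub-ps at the defaults), but collective hinge modes
    relax over nanoseconds, so the default 8 ns run with the first half
    discarded lets a restraint-driven transition complete — and lets
    unrestrained reference runs spread over the target basin — before
    production sampling starts.
    """

    temperature: float = 300.0  # K
    friction: float = 50.0  # kJ mol⁻¹ ps Å⁻²
    timestep: float = 0.02  # ps
    n_steps: int = 400000
    enm_cutoff: float = 12.0  # Å
    enm_stiffness: float = 2000.0  # kJ mol⁻¹ nm⁻²
    save_interval: int = 500
    equilibration_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not 0 <= self.equilibration_fraction < 1:
            raise ValueError("equilibration_fraction must be in [0, 1)")
        if self.timestep <= 0 or self.n_steps < 1 or self.save_interval < 1:
            raise ValueError("timestep, n_steps, save_interval must be positive")

    def check_stability(self, max_stiffness_nm2: float) -> None:
        """Fail fast if the timestep cannot integrate the stiffest spring.

        For overdamped dynamics the relative coordinate of a pair relaxes with
        rate 2k/friction; the explicit Euler step is stable (and accurate) for
        dt well below friction/(2k).
        """
        k = max(max_stiffness_nm2, self.enm_stiffness) * _NM2_TO_A2
        dt_max = 0.5 * self.friction / (2 * k) if k > 0 else np.inf
        if self.timestep > dt_max:
            raise ValueError(
                f"timestep {self.timestep} ps unstable for stiffness "
                f"{max_stiffness_nm2} kJ/mol/nm^2 (max {dt_max:.4f} ps)"
            )


@dataclass
class Trajectory:
    """Saved frames of one run with per-frame energies."""

    frames: Ensemble
    times: np.ndarray  # ps
    energies: pd.DataFrame  # columns: time_ps, total_kJ_mol, restraint_kJ_mol

    def __len__(self) -> int:
        return len(self.frames)

    def production_frames(self, equilibration_fraction: float) -> Ensemble:
        """Frames after discarding the leading equilibration fraction."""
        n = len(self.frames)
        start = int(np.floor(n * equilibration_fraction))
        start = min(start, n - 1)
        return Ensemble(structures=self.frames.structures[start:])


def build_restraints(
    pairs: Sequence[ResiduePair], target: Structure, stiffness: float = 5000.0
) -> list[RestraintTerm]:
    """One harmonic term per pair with rest length read from the target."""
    terms = []
    for p in pairs:
        bi = target.index_of(p.beta)
        di = target.index_of(p.delta)
        d = float(np.linalg.norm(target.ca_coords[bi] - target.ca_coords[di]))
        terms.append(RestraintTerm(pair=p, target_distance=d, stiffness=stiffness))
    return terms


def restraint_energy(s: Structure, restraints: Sequence[RestraintTerm]) -> float:
    """Total harmonic restraint energy of a conformation, kJ mol⁻¹."""
    total = 0.0
    for t in restraints:
        bi = s.index_of(t.pair.beta)
        di = s.index_of(t.pair.delta)
        r = float(np.linalg.norm(s.ca_coords[bi] - s.ca_coords[di]))
        k = t.stiffness * _NM2_TO_A2
        total += 0.5 * k * (r - t.target_distance) ** 2
    return total


def _pair_terms(initial: Structure, restraints: Sequence[RestraintTerm], params: EngineParams):
    """Concatenate ENM contacts and restraints into flat spring arrays."""
    enm = build_enm(
        initial, cutoff=params.enm_cutoff, spring_constant=params.enm_stiffness * _NM2_TO_A2
    )
    i_idx = list(enm.contacts[:, 0])
    j_idx = list(enm.contacts[:, 1])
    k_arr = [enm.spring_constant] * len(enm.contacts)
    r0_arr = list(enm.rest_lengths)
    n_enm = len(enm.contacts)
    for t in restraints:
        i_idx.append(initial.index_of(t.pair.beta))
        j_idx.append(initial.index_of(t.pair.delta))
        k_arr.append(t.stiffness * _NM2_TO_A2)
        r0_arr.append(t.target_distance)
    return (
        np.array(i_idx, dtype=int),
        np.array(j_idx, dtype=int),
        np.array(k_arr, dtype=float),
        np.array(r0_arr, dtype=float),
        n_enm,
    )


def run_dynamics(
    initial: Structure,
    restraints: Sequence[RestraintTerm],
    params: EngineParams,
) -> Trajectory:
    """Overdamped Langevin trajectory on ENM(initial) + restraint springs.

    Update rule per bead: ``x += (F/gamma) dt + sqrt(2 kB T dt / gamma) eta``
    with independent standard-normal ``eta``.  Deterministic given
    ``params.seed``.  Aborts with the frame index if any coordinate becomes
    non-finite.
    """
    if restraints:
        params.check_stability(max(t.stiffness for t in restraints))
    else:
        params.check_stability(0.0)
    i_idx, j_idx, k_arr, r0_arr, n_enm = _pair_terms(initial, restraints, params)

    rng = np.random.default_rng(params.seed)
    x = initial.ca_coords.copy()
    n = len(x)
    gamma = params.friction
    dt = params.timestep
    noise_scale = np.sqrt(2.0 * KB * params.temperature * dt / gamma)

    frames: list[Structure] = []
    times: list[float] = []
    e_tot: list[float] = []
    e_res: list[float] = []

    n_chunks = params.n_steps // params.save_interval
    leftover = params.n_steps % params.save_interval
    step = 0
    for chunk in range(n_chunks):
        if params.temperature > 0:
            noise = noise_scale * rng.standard_normal((params.save_interval, n, 3))
        else:
            noise = np.zeros((params.save_interval, n, 3))
        x = _integrate_chunk(x, i_idx, j_idx, k_arr, r0_arr, dt / gamma, noise)
        step += params.save_interval
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"non-finite coordinates at step {step} "
                f"(frame {len(frames)}); reduce the timestep"
            )
        d = x[i_idx] - x[j_idx]
        dist = np.sqrt(np.sum(d * d, axis=1))
        e_all = 0.5 * k_arr * (dist - r0_arr) ** 2
        frames.append(
            initial.with_coords(x, identifier=f"{initial.identifier}:t{step * dt:.1f}ps")
        )
        times.append(step * dt)
        e_tot.append(float(e_all.sum()))
        e_res.append(float(e_all[n_enm:].sum()))
    if leftover:  # trailing unsaved steps keep the step count exact
        if params.temperature > 0:
            noise = noise_scale * rng.standard_normal((leftover, n, 3))
        else:
            noise = np.zeros((leftover, n, 3))
        x = _integrate_chunk(x, i_idx, j_idx, k_arr, r0_arr, dt / gamma, noise)

    energies = pd.DataFrame(
        {"time_ps": times, "total_kJ_mol": e_tot, "restraint_kJ_mol": e_res}
    )
    return Trajectory(frames=Ensemble(structures=frames), times=np.array(times), energies=energies)


def replicate_runs(
    initial: Structure,
    restraints: Sequence[RestraintTerm],
    params: EngineParams,
    n_samples: int,
    base_seed: int | None = None,
) -> list[Trajectory]:
    """Independent replicate trajectories with seeds ``base_seed + k``.

    Each returned trajectory contains production frames only (the leading
    ``equilibration_fraction`` of saved frames is discarded), mirroring the
    protocol of discarding the pre-convergence part of each run.
    """
    if base_seed is None:
        base_seed = params.seed
    out = []
    for k in range(n_samples):
        p = replace(params, seed=base_seed + k)
        try:
            traj = run_dynamics(initial, restraints, p)
        except Exception as exc:
            raise RuntimeError(f"replicate {k} (seed {base_seed + k}) failed") from exc
        prod = traj.production_frames(params.equilibration_fraction)
        n_skip = len(traj.frames) - len(prod)
        out.append(
            Trajectory(
                frames=prod,
                times=traj.times[n_skip:],
                energies=traj.energies.iloc[n_skip:].reset_index(drop=True),
            )
        )
    return out


def make_engine(initial: Structure, params: EngineParams, n_samples: int = 1):
    """Engine handle for the iterative largest-change selection loop.

    Returns a callable mapping a restraint list to one :class:`Ensemble` of
    pooled production frames from ``n_samples`` replicate runs starting at
    ``initial``.
    """

    def engine(restraints: Sequence[RestraintTerm]) -> Ensemble:
        trajs = replicate_runs(initial, restraints, params, n_samples=n_samples)
        members = [s for t in trajs for s in t.frames]
        return Ensemble(structures=members)

    return engine


# ---------------------------------------------------------------------------
# Restraint-file export (to drive a real MD engine externally)
# ---------------------------------------------------------------------------

def export_restraints(
    restraints: Sequence[RestraintTerm],
    dialect: str = "generic-tsv",
    structure: Structure | None = None,
) -> str:
    """Serialize restraints in one of three dialects.

    ``generic-tsv``
        columns chain_i, resid_i, chain_j, resid_j, r0_nm, k_kJ_mol_nm2.
    ``gromacs-distance``
        an ``[ distance_restraints ]``-style block keyed by 1-based Cα atom
        indices resolved against ``structure`` (required).
    ``plumed``
        DISTANCE + RESTRAINT lines with AT in nm and KAPPA in kJ mol⁻¹ nm⁻².
    """
    if not restraints:
        raise ValueError("no restraints to export")
    if dialect == "generic-tsv":
        lines = ["chain_i\tresid_i\tchain_j\tresid_j\tr0_nm\tk_kJ_mol_nm2"]
        for t in restraints:
            lines.append(
                f"{t.pair.beta[0]}\t{t.pair.beta[1]}\t{t.pair.delta[0]}\t"
                f"{t.pair.delta[1]}\t{t.target_distance / 10.0:.4f}\t{t.stiffness:.1f}"
            )
        return "\n".join(lines) + "\n"
    if dialect == "gromacs-distance":
        if structure is None:
            raise ValueError("gromacs dialect needs a structure to resolve atom indices")
        lines = [
            "[ distance_restraints ]",
            "; ai aj type index type' low up1 up2 fac",
        ]
        for idx, t in enumerate(restraints):
            ai = structure.index_of(t.pair.beta) + 1
            aj = structure.index_of(t.pair.delta) + 1
            r0 = t.target_distance / 10.0
            lines.append(
                f"{ai:6d} {aj:6d} 1 {idx:4d} 2 {r0:.4f} {r0:.4f} {r0 + 0.1:.4f} 1.0"
            )
        return "\n".join(lines) + "\n"
    if dialect == "plumed":
        lines = []
        for idx, t in enumerate(restraints):
            label = f"d{idx + 1}"
            lines.append(
                f"{label}: DISTANCE ATOMS=@CA-{t.pair.beta[0]}_{t.pair.beta[1]},"
                f"@CA-{t.pair.delta[0]}_{t.pair.delta[1]}"
            )
            lines.append(
                f"r{idx + 1}: RESTRAINT ARG={label} AT={t.target_distance / 10.0:.4f} "
                f"KAPPA={t.stiffness:.1f}"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


def read_restraints_tsv(text_or_path) -> list[RestraintTerm]:
    """Parse the ``generic-tsv`` dialect back into restraint terms."""
    import io
    import os

    if isinstance(text_or_path, str) and "\t" in text_or_path:
        fh = io.StringIO(text_or_path)
    elif isinstance(text_or_path, (str, os.PathLike)):
        fh = open(text_or_path)
    else:
        fh = text_or_path
    df = pd.read_csv(fh, sep="\t")
    terms = []
    for _, row in df.iterrows():
        pair = ResiduePair(
            beta=(str(row["chain_i"]), int(row["resid_i"])),
            delta=(str(row["chain_j"]), int(row["resid_j"])),
        )
        terms.append(
            RestraintTerm(
                pair=pair,
                target_distance=float(row["r0_nm"]) * 10.0,
                stiffness=float(row["k_kJ_mol_nm2"]),
            )
        )
    return terms
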