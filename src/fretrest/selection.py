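"""Restraint-selection methods over Cα pair-separation space.

Five ways of choosing which Cα–Cα distances to restrain, all drawing from the
same FRET-feasible candidate pool (pairs separated by at least the radius of
gyration, with both residues solvent-exposed):

* random selection — the baseline;
* chi-squared-weighted greedy selection on a normal-mode ensemble;
* largest Cα separation with Pearson-correlation pruning;
* largest change in pairwise separation between initial and target
  (iterative, re-simulating after each added restraint);
* linear discriminant analysis on pair-separation feature vectors.

A :class:`SelectionResult` is nested: the first ``k`` entries are the chosen
set for ``Nr = k``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .structures import (
    Ensemble,
    Structure,
    ca_rmsd,
    distance_matrix,
    get_rsasa,
    radius_of_gyration,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResiduePair",
    "CandidatePool",
    "SelectionResult",
    "LdaModel",
    "build_candidate_pool",
    "select_random",
    "chi_squared_deviation",
    "pair_probability",
    "ensemble_weighted_rmsd",
    "select_nma",
    "select_largest_separation",
    "select_largest_delta",
    "fit_lda",
    "select_lda",
]


@dataclass(frozen=True, order=True)
class ResiduePair:
    """An unordered amino-acid pair, stored with beta before delta in chain order."""

    beta: tuple[str, int]
    delta: tuple[str, int]

    def __post_init__(self):
        if self.beta == self.delta:
            raise ValueError("a pair needs two distinct residues")

    def shares_residue(self, other: "ResiduePair") -> bool:
        return bool({self.beta, self.delta} & {other.beta, other.delta})

    @property
    def residues(self) -> set[tuple[str, int]]:
        return {self.beta, self.delta}


def _make_pair(s: Structure, i: int, j: int) -> ResiduePair:
    if i > j:
        i, j = j, i
    return ResiduePair(beta=s.residues[i].key, delta=s.residues[j].key)


@dataclass
class CandidatePool:
    """FRET-feasible amino-acid pairs on the initial structure.

    ``indices`` are positions into the structure's residue order (i < j);
    ``provenance`` records, per pair, the separation and both rSASA values
    that passed the filters.
    """

    pairs: list[ResiduePair]
    indices: np.ndarray  # (M, 2)
    structure: Structure
    provenance: pd.DataFrame
    n_total_pairs: int  # Np = N(N-1)/2

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: ResiduePair) -> bool:
        return pair in set(self.pairs)

    @property
    def fraction_of_universe(self) -> float:
        return len(self.pairs) / self.n_total_pairs

    def pair_distances(self, s: Structure) -> np.ndarray:
        """Distances of all pool pairs evaluated on one structure."""
        idx = {k: a for a, k in enumerate(s.residue_keys)}
        bi = np.array([idx[p.beta] for p in self.pairs])
        di = np.array([idx[p.delta] for p in self.pairs])
        return np.linalg.norm(s.ca_coords[bi] - s.ca_coords[di], axis=1)

    def ensemble_pair_distances(self, ensemble: Ensemble) -> np.ndarray:
        """(Ns, M) distances of all pool pairs across an ensemble."""
        idx = {k: a for a, k in enumerate(ensemble.residue_keys)}
        bi = np.array([idx[p.beta] for p in self.pairs])
        di = np.array([idx[p.delta] for p in self.pairs])
        coords = ensemble.coords
        return np.linalg.norm(coords[:, bi, :] - coords[:, di, :], axis=2)


@dataclass
class SelectionResult:
    """Nested ordered restraint list: entry k-1 is the pair added at Nr = k."""

    ordered_pairs: list[ResiduePair]
    scores: list[float]
    method: str
    params: dict = field(default_factory=dict)

    def subset(self, nr: int) -> list[ResiduePair]:
        if nr > len(self.ordered_pairs):
            raise ValueError(f"only {len(self.ordered_pairs)} pairs selected")
        return self.ordered_pairs[:nr]

    def to_frame(self, target: Structure | None = None) -> pd.DataFrame:
        rows = []
        for step, (p, sc) in enumerate(zip(self.ordered_pairs, self.scores), start=1):
            row = {
                "method": self.method,
                "step": step,
                "beta_chain": p.beta[0],
                "beta_resid": p.beta[1],
                "delta_chain": p.delta[0],
                "delta_resid": p.delta[1],
                "score": sc,
            }
            if target is not None:
                bi = target.index_of(p.beta)
                di = target.index_of(p.delta)
                row["target_distance_A"] = float(
                    np.linalg.norm(target.ca_coords[bi] - target.ca_coords[di])
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path, target: Structure | None = None) -> None:
        self.to_frame(target).to_csv(path, sep="\t", index=False)
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"method": self.method, "params": _jsonable(self.params)}, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# Candidate pool
# ---------------------------------------------------------------------------

def build_candidate_pool(
    s: Structure,
    min_separation: float | None = None,
    rsasa_min: float = 0.1,
) -> CandidatePool:
    """All FRET-feasible pairs of a structure.

    A pair survives iff its Cα separation is at least ``min_separation``
    (default: the radius of gyration, below which FRET efficiency saturates
    for common dye pairs) and both residues have rSASA >= ``rsasa_min``
    (buried residues cannot be labelled).  For globular proteins this keeps
    roughly a third of the N(N-1)/2 pair universe.
    """
    rsasa = get_rsasa(s)
    if min_separation is None:
        min_separation = radius_of_gyration(s)
    dmat = distance_matrix(s).values
    n = s.n_residues
    exposed = rsasa >= rsasa_min
    iu = np.triu_indices(n, k=1)
    ok = (dmat[iu] >= min_separation) & exposed[iu[0]] & exposed[iu[1]]
    ci, cj = iu[0][ok], iu[1][ok]
    pairs = [_make_pair(s, int(a), int(b)) for a, b in zip(ci, cj)]
    prov = pd.DataFrame(
        {
            "beta_index": ci,
            "delta_index": cj,
            "separation_A": dmat[ci, cj],
            "rsasa_beta": rsasa[ci],
            "rsasa_delta": rsasa[cj],
        }
    )
    return CandidatePool(
        pairs=pairs,
        indices=np.column_stack([ci, cj]).astype(int),
        structure=s,
        provenance=prov,
        n_total_pairs=n * (n - 1) // 2,
    )


# ---------------------------------------------------------------------------
# (a) random selection
# ---------------------------------------------------------------------------

def select_random(
    pool: CandidatePool, nr: int, n_sets: int = 100, seed: int = 0
) -> list[list[ResiduePair]]:
    """``n_sets`` uniform without-replacement draws of ``nr`` pool pairs."""
    if nr > len(pool):
        raise ValueError(f"nr={nr} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        chosen = rng.choice(len(pool), size=nr, replace=False)
        sets.append([pool.pairs[i] for i in sorted(chosen)])
    return sets


# ---------------------------------------------------------------------------
# (b) NMA-ensemble chi-squared greedy selection
# ---------------------------------------------------------------------------

def _pair_distances(s: Structure, pairs: Sequence[ResiduePair]) -> np.ndarray:
    bi = np.array([s.index_of(p.beta) for p in pairs])
    di = np.array([s.index_of(p.delta) for p in pairs])
    return np.linalg.norm(s.ca_coords[bi] - s.ca_coords[di], axis=1)


def _chi2_terms(d_i: np.ndarray, d_j: np.ndarray, convention: str) -> np.ndarray:
    """Per-pair chi-squared contributions between two distance vectors."""
    delta = d_i - d_j
    mean = 0.5 * (d_i + d_j)
    if convention == "fractional":
        return (delta / mean) ** 2
    if convention == "sum":
        return delta**2 / (d_i + d_j) ** 2
    raise ValueError(f"unknown chi-squared convention {convention!r}")


def chi_squared_deviation(
    si: Structure,
    sj: Structure,
    pairs: Sequence[ResiduePair],
    convention: str = "fractional",
) -> float:
    """Chi-squared deviation of the pair separations between two structures.

    Default convention: sum over pairs of the squared fractional deviation
    (ΔR / R̄)² with R̄ the mean of the two separations; ``convention="sum"``
    uses ΔR²/(Rⁱ+Rʲ)² instead (a factor 4 smaller per pair).
    """
    if len(pairs) == 0:
        raise ValueError("pair list must be non-empty")
    return float(np.sum(_chi2_terms(_pair_distances(si, pairs), _pair_distances(sj, pairs), convention)))


def pair_probability(chi2: float, n_pairs: int) -> float:
    """Upper-tail probability of chi-squared with ``n_pairs`` degrees of freedom."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if np.any(np.asarray(chi2) < 0):
        raise ValueError("chi2 must be >= 0")
    return chi2_dist.sf(chi2, df=n_pairs)


def _weighted_rmsd_from_matrices(chi2_mat: np.ndarray, rmsd_mat: np.ndarray, dof: int) -> float:
    """<RMSD> = mean_i [ sum_j P_ij RMSD_ij / sum_j P_ij ] with P the chi2 tail."""
    P = chi2_dist.sf(chi2_mat, df=dof)
    num = (P * rmsd_mat).sum(axis=1)
    den = P.sum(axis=1)
    # den >= 1 always: the self term j = i contributes P = 1 exactly
    return float(np.mean(num / den))


def ensemble_weighted_rmsd(
    ensemble: Ensemble,
    pairs: Sequence[ResiduePair],
    convention: str = "fractional",
    rmsd_matrix: np.ndarray | None = None,
) -> float:
    """Probability-weighted mean pairwise Cα RMSD of an ensemble.

    Structure pairs whose selected separations deviate little (high
    chi-squared tail probability) dominate; all ordered pairs including the
    self term j = i (P = 1, RMSD = 0) enter the average.
    """
    if len(pairs) == 0:
        raise ValueError("pair list must be non-empty")
    ns = len(ensemble)
    if ns < 2:
        raise ValueError("ensemble must have at least 2 members")
    dists = np.stack([_pair_distances(s, pairs) for s in ensemble])  # (Ns, k)
    chi2_mat = np.zeros((ns, ns))
    for k in range(dists.shape[1]):
        d = dists[:, k]
        chi2_mat += _chi2_terms(d[:, None], d[None, :], convention)
    if rmsd_matrix is None:
        rmsd_matrix = _aligned_rmsd_matrix(ensemble)
    return _weighted_rmsd_from_matrices(chi2_mat, rmsd_matrix, dof=len(pairs))


def _aligned_rmsd_matrix(ensemble: Ensemble) -> np.ndarray:
    ns = len(ensemble)
    mat = np.zeros((ns, ns))
    for i in range(ns):
        for j in range(i + 1, ns):
            mat[i, j] = mat[j, i] = ca_rmsd(ensemble[i], ensemble[j], align=True)
    return mat


def select_nma(
    ensemble: Ensemble,
    pool: CandidatePool,
    nr_max: int,
    subsample: int = 100,
    seed: int = 0,
    convention: str = "fractional",
) -> SelectionResult:
    """Greedy forward selection minimising the weighted ensemble RMSD.

    At step k the pool pair that, added to the k-1 already-fixed pairs,
    minimises the chi-squared-weighted mean pairwise RMSD of the ensemble is
    selected.  Per-pair chi-squared contributions are additive, so the fixed
    part is cached and each candidate costs one rank-update.

    ``subsample`` caps the number of ensemble structures used (seeded draw
    without replacement) so that the Ns² structure-pair sums stay tractable;
    the same subsample is used for every candidate and every step.
    """
    if nr_max > len(pool):
        raise ValueError("nr_max exceeds pool size")
    if nr_max == 0:
        return SelectionResult([], [], "nma", {"subsample": subsample, "seed": seed})

    rng = np.random.default_rng(seed)
    ns = len(ensemble)
    if ns > subsample:
        keep = np.sort(rng.choice(ns, size=subsample, replace=False))
        sub = Ensemble(structures=[ensemble[i] for i in keep])
    else:
        sub = ensemble

    rmsd_mat = _aligned_rmsd_matrix(sub)
    dists = pool.ensemble_pair_distances(sub)  # (S, M)
    S, M = dists.shape
    # chi2 contribution of each candidate pair, per structure pair: (M, S, S)
    # kept as per-candidate S×S slabs to bound memory
    base = np.zeros((S, S))
    selected: list[int] = []
    scores: list[float] = []
    for step in range(1, nr_max + 1):
        best_score, best_m = np.inf, -1
        for m in range(M):
            if m in selected:
                continue
            d = dists[:, m]
            contrib = _chi2_terms(d[:, None], d[None, :], convention)
            score = _weighted_rmsd_from_matrices(base + contrib, rmsd_mat, dof=step)
            # pool pairs are lexicographically ordered, so the first strict
            # minimum realises the deterministic tie-break
            if score < best_score:
                best_score, best_m = score, m
        d = dists[:, best_m]
        base = base + _chi2_terms(d[:, None], d[None, :], convention)
        selected.append(best_m)
        scores.append(best_score)
    return SelectionResult(
        ordered_pairs=[pool.pairs[m] for m in selected],
        scores=scores,
        method="nma",
        params={"subsample": subsample, "seed": seed, "convention": convention},
    )


# ---------------------------------------------------------------------------
# (c) largest Cα separation with correlation pruning
# ---------------------------------------------------------------------------

def select_largest_separation(
    s: Structure,
    trajectory: Ensemble,
    pool: CandidatePool,
    nr_max: int,
    rho_max: float = 0.9,
) -> SelectionResult:
    """Largest-separation pairs, pruned of correlated and residue-sharing ones.

    Pairs are ranked by descending Cα separation on the initial structure; a
    candidate is skipped if its pair-distance time series over the unrestrained
    trajectory has |Pearson rho| >= ``rho_max`` with any already-selected pair,
    or if it shares a residue with one.
    """
    if len(trajectory) < 2:
        raise ValueError("need at least 2 trajectory frames for correlations")
    static = pool.pair_distances(s)
    series = pool.ensemble_pair_distances(trajectory)  # (T, M)
    order = np.argsort(-static, kind="stable")

    selected: list[int] = []
    scores: list[float] = []
    for m in order:
        if len(selected) == nr_max:
            break
        cand = pool.pairs[m]
        if any(cand.shares_residue(pool.pairs[k]) for k in selected):
            continue
        redundant = False
        for k in selected:
            rho = _pearson(series[:, m], series[:, k])
            if abs(rho) >= rho_max:
                redundant = True
                break
        if redundant:
            continue
        selected.append(int(m))
        scores.append(float(static[m]))
    if len(selected) < nr_max:
        logger.warning(
            "only %d admissible pairs found (nr_max=%d)", len(selected), nr_max
        )
    return SelectionResult(
        ordered_pairs=[pool.pairs[m] for m in selected],
        scores=scores,
        method="largest_separation",
        params={"rho_max": rho_max},
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# (d) largest change in pairwise separation (iterative, engine in the loop)
# ---------------------------------------------------------------------------

def select_largest_delta(
    initial: Structure,
    target: Structure,
    engine: Callable,
    pool: CandidatePool,
    nr_max: int,
    stiffness: float = 5000.0,
) -> SelectionResult:
    """Iterative selection of the pairs deviating most from the target.

    Loop: simulate with the current restraints, average each pool pair's
    separation over the trajectory, and add the pair with the largest absolute
    deviation from its target separation (excluding pairs sharing a residue
    with one already selected), restrained to the target value.  The engine is
    any callable mapping a restraint list to an :class:`Ensemble` of
    production frames.
    """
    from .dynamics import build_restraints

    target_d = pool.pair_distances(target)
    selected: list[int] = []
    scores: list[float] = []
    for step in range(nr_max):
        pairs = [pool.pairs[m] for m in selected]
        restraints = build_restraints(pairs, target, stiffness=stiffness)
        try:
            frames = engine(restraints)
        except Exception as exc:
            raise RuntimeError(f"dynamics engine failed at selection step {step + 1}") from exc
        mean_d = pool.ensemble_pair_distances(frames).mean(axis=0)
        dev = np.abs(mean_d - target_d)
        admissible = np.ones(len(pool), dtype=bool)
        for k in selected:
            admissible &= np.array(
                [not pool.pairs[m].shares_residue(pool.pairs[k]) for m in range(len(pool))]
            )
        if not admissible.any():
            logger.warning("no admissible pairs left at step %d", step + 1)
            break
        dev_masked = np.where(admissible, dev, -np.inf)
        # pool pairs are lexicographically ordered: first maximum = tie-break
        best = int(np.flatnonzero(dev_masked == dev_masked.max())[0])
        selected.append(best)
        scores.append(float(dev[best]))
    return SelectionResult(
        ordered_pairs=[pool.pairs[m] for m in selected],
        scores=scores,
        method="largest_delta",
        params={"stiffness": stiffness},
    )


# ---------------------------------------------------------------------------
# (e) linear discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class LdaModel:
    """Rank-one LDA over pair-separation feature space.

    ``direction`` is the unit vector Ŵ maximising the Rayleigh ratio
    Ŵᵀ S_b Ŵ / Ŵᵀ S_w Ŵ, with S_b the outer product of the ensemble-mean
    difference (rank one) and S_w the pooled within-ensemble scatter.
    """

    feature_pairs: list[ResiduePair]
    mean_A: np.ndarray
    mean_B: np.ndarray
    Sw: np.ndarray
    direction: np.ndarray
    eigenvalue: float
    regularization: float

    @property
    def Sb(self) -> np.ndarray:
        diff = self.mean_A - self.mean_B
        return np.outer(diff, diff)


class NoDiscriminantError(ValueError):
    """Raised when the two ensembles have identical feature means (S_b = 0)."""


def fit_lda(
    ensemble_A: Ensemble,
    ensemble_B: Ensemble,
    pool: CandidatePool,
    regularization: float | None = None,
) -> LdaModel:
    """Fit the discriminant direction separating two conformational ensembles.

    Features are the pool pair separations of each frame.  Because S_b is rank
    one, the leading eigenvector of (S_w + εI)⁻¹ S_b is, in closed form, the
    normalised (S_w + εI)⁻¹ (mean_A − mean_B); ε defaults to
    1e-6 · trace(S_w)/dim, which regularises the generic case of more features
    than frames.
    """
    if len(ensemble_A) < 2 or len(ensemble_B) < 2:
        raise ValueError("both ensembles need at least 2 frames")
    XA = pool.ensemble_pair_distances(ensemble_A)
    XB = pool.ensemble_pair_distances(ensemble_B)
    mean_A, mean_B = XA.mean(axis=0), XB.mean(axis=0)
    diff = mean_A - mean_B
    if np.allclose(diff, 0):
        raise NoDiscriminantError("ensemble feature means are identical; Sb = 0")
    Ac, Bc = XA - mean_A, XB - mean_B
    Sw = Ac.T @ Ac + Bc.T @ Bc
    dim = Sw.shape[0]
    if regularization is None:
        regularization = 1e-6 * np.trace(Sw) / dim
        if regularization == 0:
            regularization = 1e-12
    w = np.linalg.solve(Sw + regularization * np.eye(dim), diff)
    w /= np.linalg.norm(w)
    num = float((w @ diff) ** 2)
    den = float(w @ Sw @ w)
    lam = num / den if den > 0 else np.inf
    return LdaModel(
        feature_pairs=list(pool.pairs),
        mean_A=mean_A,
        mean_B=mean_B,
        Sw=Sw,
        direction=w,
        eigenvalue=lam,
        regularization=float(regularization),
    )


def select_lda(model: LdaModel, nr_max: int) -> SelectionResult:
    """Pairs ranked by the magnitude of their discriminant weight."""
    if nr_max > len(model.feature_pairs):
        raise ValueError("nr_max exceeds feature count")
    weights = np.abs(model.direction)
    order = sorted(
        range(len(weights)),
        key=lambda m: (-weights[m], model.feature_pairs[m]),
    )[:nr_max]
    return SelectionResult(
        ordered_pairs=[model.feature_pairs[m] for m in order],
        scores=[float(weights[m]) for m in order],
        method="lda",
        params={"regularization": model.regularization, "eigenvalue": model.eigenvalue},
    )
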