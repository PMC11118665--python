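import numpy as np
import pytest

import fretrest as fr
from fretrest.dynamics import EngineParams
from fretrest.structures import ResidueInfo, Structure


def toy_structure(coords, identifier="toy", chain="A", rsasa=None, resnames=None):
    """Bare Cα structure from a coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    resnames = resnames or ["ALA"] * n
    return Structure(
        identifier=identifier,
        residues=[ResidueInfo(i + 1, chain, resnames[i]) for i in range(n)],
        ca_coords=coords,
        rsasa=None if rsasa is None else np.asarray(rsasa, dtype=float),
    )


def _rotvec_to_matrix(v):
    a = np.linalg.norm(v)
    if a < 1e-14:
        return np.eye(3)
    ax = v / a
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def rotation_grid_min_rmsd(P, Q):
    """Brute-force minimum RMSD over proper rotations, independent of SVD.

    Rotations are parameterised as axis-angle vectors in the pi-ball; a coarse
    uniform grid is refined around the running optimum down to well below a
    degree, so the result is accurate to ~1e-4 in RMSD near the optimum.
    """
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)

    def rmsd_at(v):
        d = P @ _rotvec_to_matrix(v).T - Q
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    lin = np.linspace(-np.pi, np.pi, 17)
    best_v, best = None, np.inf
    for vx in lin:
        for vy in lin:
            for vz in lin:
                v = np.array([vx, vy, vz])
                if np.linalg.norm(v) > np.pi:
                    continue
                r = rmsd_at(v)
                if r < best:
                    best, best_v = r, v
    width = lin[1] - lin[0]
    for _ in range(8):  # halve the cell around the optimum each round
        width /= 2
        offsets = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        for off in offsets * width:
            r = rmsd_at(best_v + off)
            if r < best:
                best, best_v = r, best_v + off
    return best


@pytest.fixture(scope="session")
def hinge_pair():
    return fr.make_hinge_pair(fr.HingeSpec(seed=0))


@pytest.fixture(scope="session")
def hinge_pool(hinge_pair):
    return fr.build_candidate_pool(hinge_pair[0])


@pytest.fixture
def fast_params():
    """Short engine runs for unit tests (not the production protocol)."""
    return EngineParams(n_steps=4000, save_interval=50, equilibration_fraction=0.25, seed=7)
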