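"""Shared fixtures: small hand-built trees and a session-scoped large
synthetic phylogeny with Brownian trait optima (reused by the slower
calibration tests so the tree is simulated once)."""

import numpy as np
import pandas as pd
import pytest

import phylocomm as pc
from phylocomm.io import parse_tree_newick


@pytest.fixture(scope="session")
def balanced4():
    return parse_tree_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def dm4(balanced4):
    return pc.cophenetic_distances(balanced4)


@pytest.fixture(scope="session")
def big_tree():
    return pc.simulate_yule_tree(500, 101)


@pytest.fixture(scope="session")
def big_dm(big_tree):
    return pc.cophenetic_distances(big_tree)


@pytest.fixture(scope="session")
def big_optima(big_tree):
    return pc.evolve_trait_bm(big_tree, 1.0, 0.0, 102)


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately written as plain double loops

def naive_alpha_mpd(f: dict, d: dict) -> float:
    present = [i for i, v in f.items() if v > 0]
    tot = sum(f[i] for i in present)
    val = 0.0
    for i in present:
        partners = [j for j in present if j != i]
        val += (f[i] / tot) * sum(d[(i, j)] for j in partners) / len(partners)
    return val


def naive_beta_mpd(f1: dict, f2: dict, d: dict) -> float:
    p1 = {i: v for i, v in f1.items() if v > 0}
    p2 = {j: v for j, v in f2.items() if v > 0}
    t1, t2 = sum(p1.values()), sum(p2.values())
    return sum((a / t1) * (b / t2) * d[(i, j)]
               for i, a in p1.items() for j, b in p2.items())


def naive_c_score(matrix: np.ndarray) -> float:
    n = matrix.shape[0]
    cus = []
    for i in range(n):
        for j in range(i + 1, n):
            ri = int(matrix[i].sum())
            rj = int(matrix[j].sum())
            s = int((matrix[i] & matrix[j]).sum())
            cus.append((ri - s) * (rj - s))
    return float(np.mean(cus))


def distance_dict(dm: pc.DistanceMatrix) -> dict:
    return {(a, b): dm.values[i, j]
            for i, a in enumerate(dm.ids) for j, b in enumerate(dm.ids)}
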