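"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own matching machinery:
isomorphism and embedding enumeration are done by exhaustive search over
injective index maps, and activity propagation by a plain worklist
closure, so they can serve as ground truth for the implementation.
"""

from __future__ import annotations

import itertools

import pytest

from rxntemplates import fixtures as fx
from rxntemplates.molgraph import Fragment, MolecularGraph
from rxntemplates.templates import extract_template


# ---------------------------------------------------------------------------
# Brute-force oracles


def brute_force_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Exhaustive permutation search for a label/edge-preserving bijection."""
    if g1.n_atoms != g2.n_atoms or g1.charge != g2.charge:
        return False
    n = g1.n_atoms
    for perm in itertools.permutations(range(n)):
        if any(g1.elements[i] != g2.elements[perm[i]] or
               g1.stereo[i] != g2.stereo[perm[i]] for i in range(n)):
            continue
        mapped = {tuple(sorted((perm[a], perm[b]))) for a, b in g1.bonds}
        if mapped == set(g2.bonds):
            return True
    return False


def brute_force_embeddings(pattern: Fragment, host: MolecularGraph):
    """All injective label/edge-compatible maps, as a set of mapping tuples
    (pattern atom p -> host atom tuple[p]); no symmetry collapse."""
    k, n = pattern.n_atoms, host.n_atoms
    out = set()
    for combo in itertools.permutations(range(n), k):
        ok = all(
            host.elements[combo[p]] == pattern.elements[p]
            and host.shapes[combo[p]] in pattern.allowed_shapes[p]
            for p in range(k))
        if not ok:
            continue
        if all(tuple(sorted((combo[a], combo[b]))) in host.bonds
               for a, b in pattern.bonds):
            out.add(combo)
    return out


def brute_force_pattern_automorphisms(pattern: Fragment):
    """Pattern self-maps preserving labels and bonds, by exhaustion."""
    k = pattern.n_atoms
    autos = []
    for perm in itertools.permutations(range(k)):
        if any(pattern.elements[p] != pattern.elements[perm[p]] or
               pattern.allowed_shapes[p] != pattern.allowed_shapes[perm[p]]
               for p in range(k)):
            continue
        if {tuple(sorted((perm[a], perm[b]))) for a, b in pattern.bonds} \
                == set(pattern.bonds):
            autos.append(perm)
    return autos


def bfs_activity_closure(net, cfg, seeds):
    """Independent worklist implementation of the activity fixpoint."""
    active = set(k for k in seeds if k in net.compounds)
    queue = list(active)
    # keep sweeping until no direction fires anything new
    while True:
        fired = False
        for r in net.reactions:
            for lhs, rhs, barrier, energy in (
                (r.lhs, r.rhs, r.barrier_fwd, r.reaction_energy),
                (r.rhs, r.lhs, r.barrier_bwd,
                 None if r.reaction_energy is None else -r.reaction_energy),
            ):
                if barrier is None or energy is None:
                    continue
                if barrier >= cfg.barrier_active_max:
                    continue
                if energy >= cfg.energy_active_max:
                    continue
                if set(lhs) <= active and not set(rhs) <= active:
                    active |= set(rhs)
                    fired = True
        if not fired:
            return active


# ---------------------------------------------------------------------------
# Common fixtures


@pytest.fixture(scope="session")
def da_reaction():
    return fx.diels_alder()


@pytest.fixture(scope="session")
def sn2_reaction():
    return fx.sn2()


@pytest.fixture(scope="session")
def da_template(da_reaction):
    return extract_template(da_reaction, label="diels_alder")


@pytest.fixture(scope="session")
def sn2_template(sn2_reaction):
    return extract_template(sn2_reaction, label="sn2")


@pytest.fixture(scope="session")
def peo():
    return fx.peo_system()


@pytest.fixture(scope="session")
def ppo():
    return fx.ppo_system()


@pytest.fixture(scope="session")
def hydride_template():
    return extract_template(fx.hydride_abstraction(), label="hydride")
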