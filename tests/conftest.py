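import numpy as np
import pytest

from adductgraph import (
    PROTON_MASS,
    Peak,
    Spectrum,
    build_graph,
    expand_species_closure,
    reference_fixtures,
)
from adductgraph.filters import clean
from adductgraph.ranking import annotate_spectrum


@pytest.fixture(scope="session")
def default_closure():
    return expand_species_closure()


@pytest.fixture(scope="session")
def lc_fixture_result():
    spec = clean(reference_fixtures()["lc_proline_mix"])
    g = build_graph(spec)
    return spec, g, annotate_spectrum(spec, g)


@pytest.fixture(scope="session")
def fia_fixture_result():
    spec = clean(reference_fixtures()["fia_proline"])
    g = build_graph(spec)
    return spec, g, annotate_spectrum(spec, g)


def brute_force_edges(spectrum, closure, tol):
    """Independent O(n^2) oracle for the graph builder.

    For every ordered peak pair and every closure species, tests the match
    directly; keeps, per pair, the minimal-|error| species (label ties broken
    alphabetically, mirroring the builder's documented convention).
    """
    peaks = spectrum.retained
    best = {}
    for i, p in enumerate(peaks):
        neutral = p.mz - PROTON_MASS
        if neutral <= 0:
            continue
        for j, q in enumerate(peaks):
            if i == j:
                continue
            for sp in closure:
                if sp.multimer_n == 1 and not sp.delta_counts:
                    continue
                err = q.mz - (sp.multimer_n * neutral + sp.mass_offset)
                if abs(err) <= tol:
                    key = (i, j)
                    cand = (abs(err), sp.label, err)
                    if key not in best or cand < best[key]:
                        best[key] = cand
    return {(i, j): (label, err) for (i, j), (_, label, err) in best.items()}


def graph_edge_map(spectrum, g):
    index = {p: i for i, p in enumerate(spectrum.retained)}
    return {
        (index[u], index[v]): (d["label"], d["mass_error"])
        for u, v, d in g.digraph.edges(data=True)
    }


def random_spectrum(rng, n_peaks=None, mz_range=(80.0, 500.0)):
    n = n_peaks or int(rng.integers(2, 51))
    mzs = rng.uniform(*mz_range, size=n)
    intens = rng.uniform(500.0, 1e5, size=n)
    return Spectrum([Peak(float(m), float(i)) for m, i in zip(mzs, intens)])
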