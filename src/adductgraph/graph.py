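"""Directed weighted annotation graph over a filtered centroid spectrum.

Every retained peak is treated as a putative [M+H]+ of neutral mass
``mz - proton``; any other peak that matches a closure species of that neutral
mass within the absolute tolerance receives an edge.  Edge direction encodes
the annotation sense: protonated → adducted, precursor → neutral-loss product,
monomer → multimer.  When a peak pair is linked in both directions (the
adduct-versus-loss ambiguity of ±NH3), both arcs are kept and marked
undirected, forming a single bidirectional relation.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .chem import (
    PROTON_MASS,
    AnnotationDelta,
    IonSpecies,
    expand_species_closure,
    species_delta,
)
from .io import Peak, Spectrum

__all__ = ["AnnotationGraph", "match_delta", "build_graph"]

DEFAULT_TOLERANCE = 0.010  # Da (10 mmu)


@dataclass
class AnnotationGraph:
    """A spectrum's annotation network plus the parameters that produced it."""

    spectrum: Spectrum
    digraph: nx.DiGraph
    tolerance: float
    closure: Sequence[IonSpecies]

    @property
    def peaks(self) -> list:
        return list(self.digraph.nodes)

    def edges(self):
        return self.digraph.edges(data=True)

    # -- export -------------------------------------------------------------

    def _export_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for p in self.digraph.nodes:
            g.add_node(f"{p.mz:.4f}", mz=float(p.mz), intensity=float(p.intensity))
        for u, v, data in self.digraph.edges(data=True):
            g.add_edge(
                f"{u.mz:.4f}",
                f"{v.mz:.4f}",
                label=data["label"],
                mass_error_mmu=round(data["mass_error"] * 1000.0, 3),
                directed=bool(data["directed"]),
            )
        return g

    def to_graphml(self, path: str) -> None:
        nx.write_graphml(self._export_graph(), path)

    def to_dot(self, path: str) -> None:
        g = self._export_graph()
        lines = ["digraph annotation {"]
        for n, attrs in g.nodes(data=True):
            lines.append(
                f'  "{n}" [mz={attrs["mz"]:.4f}, intensity={attrs["intensity"]:.1f}];'
            )
        for u, v, attrs in g.edges(data=True):
            style = "" if attrs["directed"] else ", dir=both"
            lines.append(
                f'  "{u}" -> "{v}" [label="{attrs["label"]} '
                f'({attrs["mass_error_mmu"]:+.1f} mmu)"{style}];'
            )
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def match_delta(
    observed: float,
    closure: Sequence[IonSpecies],
    tol: float = DEFAULT_TOLERANCE,
) -> list[AnnotationDelta]:
    """Interpret an observed m/z shift between two peaks of one analyte.

    Matches the shift against all monomer closure species relative to [M+H]+,
    returning relations sorted by absolute mass error.  A shift whose negation
    is also in the closure (ammonium adduct versus ammonia loss) is genuinely
    ambiguous in direction, and both interpretations are returned undirected.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    protonated = IonSpecies.protonated(1)
    offsets = {}
    for sp in closure:
        if sp.multimer_n != 1:
            continue
        offsets[sp] = species_delta(protonated, sp)
    matches = []
    for sp, delta in offsets.items():
        if sp == protonated:
            continue
        err = observed - delta
        if abs(err) <= tol:
            ambiguous = any(
                other != sp and abs(d + delta) <= 1e-9 for other, d in offsets.items()
            )
            matches.append(
                (
                    abs(err),
                    AnnotationDelta(protonated, sp, delta, directed=not ambiguous),
                )
            )
            if ambiguous:
                # mirrored reading: the *upper* peak is the [M+H]+ and the
                # observed pair is a neutral loss from it (or vice versa)
                mirror = next(
                    other for other, d in offsets.items()
                    if other != sp and abs(d + delta) <= 1e-9
                )
                matches.append(
                    (abs(err), AnnotationDelta(protonated, mirror, -delta, directed=False))
                )
    matches.sort(key=lambda t: (t[0], t[1].to_species.label))
    return [m for _, m in matches]


def build_graph(
    s: Spectrum,
    closure: Sequence[IonSpecies] | None = None,
    tol: float = DEFAULT_TOLERANCE,
) -> AnnotationGraph:
    """Build the annotation graph of a filtered, deisotoped spectrum.

    For every retained peak P taken as [M+H]+ with M = P.mz − proton, every
    other retained peak within ``tol`` of ``ion_mz(M, species)`` for a closure
    species receives the edge P → peak.  When several closure species match the
    same peak pair, the minimal-|error| relation labels the edge and the
    alternates are kept on the edge for re-interpretation workflows.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if closure is None:
        closure = expand_species_closure()
    peaks = s.retained
    g = nx.DiGraph()
    for p in peaks:
        g.add_node(p)
    mzs = [p.mz for p in peaks]

    candidates: dict[tuple[int, int], list[tuple[float, IonSpecies]]] = {}
    for i, p in enumerate(peaks):
        neutral = p.mz - PROTON_MASS
        if neutral <= 0:
            continue
        for sp in closure:
            if sp.multimer_n == 1 and not sp.delta_counts:
                continue  # identity
            target = sp.ion_mz(neutral)
            lo = bisect.bisect_left(mzs, target - tol)
            hi = bisect.bisect_right(mzs, target + tol)
            for j in range(lo, hi):
                if j == i:
                    continue
                candidates.setdefault((i, j), []).append((mzs[j] - target, sp))

    for (i, j), hits in candidates.items():
        hits.sort(key=lambda t: (abs(t[0]), t[1].label))
        err, sp = hits[0]
        g.add_edge(
            peaks[i],
            peaks[j],
            label=sp.label,
            species=sp,
            mass_error=err,
            multimer_n=sp.multimer_n,
            directed=True,
            alternates=[(alt.label, e) for e, alt in hits[1:]],
        )

    # ambiguity pass: a pair annotated in both directions has no defined sense
    for u, v in list(g.edges):
        if g.has_edge(v, u):
            g[u][v]["directed"] = False
            g[v][u]["directed"] = False

    return AnnotationGraph(spectrum=s, digraph=g, tolerance=tol, closure=list(closure))
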