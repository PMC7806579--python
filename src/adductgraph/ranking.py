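"""Cluster partitioning, [M+H]+ candidate ranking, and confidence indexes.

A cluster is a weakly connected component of the annotation graph.  Within a
cluster, each peak's *explained* set is itself plus the peaks it annotates
directly (bidirectional ±NH3 relations count both ways); the candidate is the
peak with the largest explained TIC, ties resolved by connectivity, then by
summed |mass error| of its outgoing annotations, then by lowest m/z.  The
connectivity convention is self-exclusive — a peak that annotates two others
has connectivity 2, a peak that explains only itself has connectivity 0 — so
ties are unaffected by the ±1 choice.

Three indexes qualify each candidate: CGC (cluster global connectivity, the
number of ions in the cluster), CIC (cluster intensity coverage, percent of the
spectrum TIC in the cluster) and CCC (cluster count coverage, percent of the
retained peak count in the cluster).  Summed over all clusters, singletons
included, CIC and CCC are 100% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .chem import PROTON_MASS
from .graph import AnnotationGraph
from .io import Peak, Spectrum

__all__ = [
    "Cluster",
    "CandidateRecord",
    "HeterodimerFlag",
    "SpectrumAnnotation",
    "clusters",
    "explain",
    "rank_candidates",
    "cluster_indexes",
    "annotate_spectrum",
    "candidate_table",
    "annotation_table",
    "singleton_table",
    "heterodimer_scan",
]


@dataclass
class Cluster:
    member_peaks: list
    cluster_id: int
    is_singleton: bool

    def __post_init__(self) -> None:
        self.member_peaks = sorted(self.member_peaks, key=lambda p: p.mz)
        self.is_singleton = len(self.member_peaks) == 1

    @property
    def intensity(self) -> float:
        return float(sum(p.intensity for p in self.member_peaks))

    def __len__(self) -> int:
        return len(self.member_peaks)


@dataclass
class CandidateRecord:
    """A cluster's best [M+H]+ candidate with its confidence indexes."""

    candidate_mz: float
    explained_tic: float
    connectivity: int
    cgc: int
    cic: float
    ccc: float
    cluster_id: int
    alternates: list = field(default_factory=list)
    peak: Peak | None = None
    cluster: Cluster | None = None


@dataclass(frozen=True)
class HeterodimerFlag:
    """A peak consistent with a proton-bound dimer of two candidates."""

    peak_mz: float
    candidate_a_mz: float
    candidate_b_mz: float
    mass_error: float


def clusters(g: AnnotationGraph) -> list[Cluster]:
    """Weakly connected components, ids assigned by ascending minimum m/z."""
    comps = [sorted(c, key=lambda p: p.mz) for c in nx.weakly_connected_components(g.digraph)]
    comps.sort(key=lambda c: c[0].mz)
    return [Cluster(c, cluster_id=i, is_singleton=len(c) == 1) for i, c in enumerate(comps)]


def explain(node: Peak, cluster: Cluster, g: AnnotationGraph) -> tuple[float, int]:
    """Explained TIC and connectivity of ``node`` within its cluster.

    The explained set is the node plus its direct annotation targets; TIC sums
    the set's intensities (node included), connectivity counts the set minus
    the node itself.
    """
    if node not in cluster.member_peaks:
        raise ValueError("node is not a member of the given cluster")
    reached = _explained_set(node, g)
    # summation in m/z order keeps the float result independent of set order
    tic = float(sum(p.intensity for p in sorted(reached, key=lambda p: p.mz)))
    return tic, len(reached) - 1


def _explained_set(node: Peak, g: AnnotationGraph) -> set:
    return {node} | set(g.digraph.successors(node))


def rank_candidates(cluster: Cluster, g: AnnotationGraph) -> CandidateRecord:
    """Pick the cluster's [M+H]+ candidate.

    Ranking is by explained TIC, then connectivity, then lowest summed
    |mass error| over outgoing edges, then lowest m/z.  Singleton clusters are
    not ranked — they are reported separately as unexplained putatives.
    """
    if cluster.is_singleton:
        raise ValueError("singleton clusters are not ranked; see singleton_table")

    def sort_key(p: Peak):
        tic, conn = explain(p, cluster, g)
        err_sum = sum(abs(d["mass_error"]) for _, _, d in g.digraph.out_edges(p, data=True))
        return (-tic, -conn, err_sum, p.mz)

    ordered = sorted(cluster.member_peaks, key=sort_key)
    best = ordered[0]
    best_tic, best_conn = explain(best, cluster, g)
    tied = [
        p
        for p in cluster.member_peaks
        if p is not best and explain(p, cluster, g)[0] == best_tic
    ]
    return CandidateRecord(
        candidate_mz=best.mz,
        explained_tic=best_tic,
        connectivity=best_conn,
        cgc=len(cluster),
        cic=float("nan"),
        ccc=float("nan"),
        cluster_id=cluster.cluster_id,
        alternates=tied,
        peak=best,
        cluster=cluster,
    )


def cluster_indexes(cluster: Cluster, s: Spectrum) -> tuple[int, float, float]:
    """(CGC, CIC %, CCC %) of a cluster against its filtered, deisotoped spectrum."""
    tic = s.tic
    n_retained = len(s.retained)
    if tic <= 0 or n_retained == 0:
        raise ValueError("cannot compute coverage indexes on a zero-TIC spectrum")
    cgc = len(cluster)
    cic = 100.0 * cluster.intensity / tic
    ccc = 100.0 * cgc / n_retained
    return cgc, cic, ccc


# ---------------------------------------------------------------------------
# High-level per-spectrum annotation result
# ---------------------------------------------------------------------------


@dataclass
class SpectrumAnnotation:
    """Everything the pipeline derives from one spectrum."""

    spectrum: Spectrum
    graph: AnnotationGraph
    clusters: list
    candidates: list
    singletons: list
    heterodimers: list = field(default_factory=list)

    @property
    def n_putative(self) -> int:
        """Cluster candidates plus singleton putatives — the reduced [M+H]+ count."""
        return len(self.candidates) + len(self.singletons)


def annotate_spectrum(
    s: Spectrum,
    g: AnnotationGraph,
    scan_heterodimers: bool = True,
) -> SpectrumAnnotation:
    """Cluster a built graph, rank candidates, and attach indexes."""
    parts = clusters(g)
    cands = []
    singles = []
    for cl in parts:
        if cl.is_singleton:
            singles.append(cl.member_peaks[0])
            continue
        rec = rank_candidates(cl, g)
        rec.cgc, rec.cic, rec.ccc = cluster_indexes(cl, s)
        cands.append(rec)
    result = SpectrumAnnotation(
        spectrum=s, graph=g, clusters=parts, candidates=cands, singletons=singles
    )
    if scan_heterodimers:
        result.heterodimers = heterodimer_scan(s, cands, g.tolerance)
    return result


def candidate_table(results: Iterable[SpectrumAnnotation]) -> pd.DataFrame:
    """One row per ranked [M+H]+ candidate across a batch."""
    rows = []
    for res in results:
        for rec in res.candidates:
            members = rec.cluster.member_peaks if rec.cluster else []
            rows.append(
                {
                    "spectrum": res.spectrum.title,
                    "candidate_mz": round(rec.candidate_mz, 4),
                    "neutral_mass": round(rec.candidate_mz - PROTON_MASS, 4),
                    "explained_tic": round(rec.explained_tic, 1),
                    "connectivity": rec.connectivity,
                    "cgc": rec.cgc,
                    "cic_percent": round(rec.cic, 1),
                    "ccc_percent": round(rec.ccc, 1),
                    "cluster_id": rec.cluster_id,
                    "cluster_members": ";".join(f"{p.mz:.4f}" for p in members),
                }
            )
    columns = [
        "spectrum", "candidate_mz", "neutral_mass", "explained_tic", "connectivity",
        "cgc", "cic_percent", "ccc_percent", "cluster_id", "cluster_members",
    ]
    return pd.DataFrame(rows, columns=columns)


def annotation_table(results: Iterable[SpectrumAnnotation]) -> pd.DataFrame:
    """One row per annotation edge across a batch; mass errors in signed mmu."""
    rows = []
    for res in results:
        for u, v, data in res.graph.digraph.edges(data=True):
            rows.append(
                {
                    "spectrum": res.spectrum.title,
                    "parent_mz": round(u.mz, 4),
                    "child_mz": round(v.mz, 4),
                    "label": data["label"],
                    "mass_error_mmu": round(data["mass_error"] * 1000.0, 2),
                    "directed": bool(data["directed"]),
                    "alternates": ";".join(lbl for lbl, _ in data.get("alternates", [])),
                }
            )
    columns = [
        "spectrum", "parent_mz", "child_mz", "label",
        "mass_error_mmu", "directed", "alternates",
    ]
    return pd.DataFrame(rows, columns=columns)


def singleton_table(results: Iterable[SpectrumAnnotation]) -> pd.DataFrame:
    """Unexplained [M+H]+ putatives — singleton ions listed outside the ranking."""
    rows = [
        {
            "spectrum": res.spectrum.title,
            "mz": round(p.mz, 4),
            "intensity": round(p.intensity, 1),
        }
        for res in results
        for p in res.singletons
    ]
    return pd.DataFrame(rows, columns=["spectrum", "mz", "intensity"])


def heterodimer_scan(
    spectrum: Spectrum,
    candidates: Sequence[CandidateRecord],
    tol: float,
) -> list[HeterodimerFlag]:
    """Flag peaks consistent with proton-bound heterodimers of candidate pairs.

    For candidates A and B with neutral masses MA and MB, a retained peak near
    ``MA + MB + proton`` (i.e. ``mzA + mzB − proton``) is flagged.  Diagnostic
    only: flagged peaks are never merged into clusters.
    """
    flags = []
    cands = sorted(candidates, key=lambda r: r.candidate_mz)
    for i, a in enumerate(cands):
        for b in cands[i + 1:]:
            target = a.candidate_mz + b.candidate_mz - PROTON_MASS
            for p in spectrum.retained:
                if p is a.peak or p is b.peak:
                    continue
                err = p.mz - target
                if abs(err) <= tol:
                    flags.append(
                        HeterodimerFlag(
                            peak_mz=p.mz,
                            candidate_a_mz=a.candidate_mz,
                            candidate_b_mz=b.candidate_mz,
                            mass_error=err,
                        )
                    )
    return flags
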