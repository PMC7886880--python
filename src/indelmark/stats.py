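"""Marker panel statistics and phylogenetics.

Implements the PowerMarker-style locus summaries used to characterize a
marker panel — major allele frequency, gene diversity (expected
heterozygosity), observed heterozygosity and Botstein's polymorphism
information content (PIC) — plus Nei's minimum genetic distance between
lines and UPGMA clustering of the resulting distance matrix.

Allele frequencies count allele copies: a homozygote contributes two copies
of its band, a heterozygote one copy of each; missing calls are excluded
from the denominator.  Within-line frequencies for the distance are 1 for a
homozygote's allele and 0.5/0.5 for a heterozygote.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genotypes import GenotypeMatrix
from .types import MarkerSummary


# ---------------------------------------------------------------------------
# Per-marker statistics
# ---------------------------------------------------------------------------

def allele_frequencies(matrix: GenotypeMatrix, marker: str) -> dict[int, float]:
    """Population allele frequencies at one marker (copy counting)."""
    counts: Counter = Counter()
    for call in matrix.marker_calls(marker).values():
        if call is None:
            continue
        if len(call) == 1:
            (allele,) = call
            counts[allele] += 2
        else:
            for allele in call:
                counts[allele] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    return {allele: counts[allele] / total for allele in sorted(counts)}


def gene_diversity(frequencies: Mapping) -> float:
    """Expected heterozygosity 1 - sum(p_i^2), no small-sample correction."""
    p = np.asarray(list(frequencies.values()), dtype=float)
    _check_simplex(p)
    return float(1.0 - np.sum(p**2))


def pic(frequencies: Mapping) -> float:
    """Botstein polymorphism information content.

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = np.asarray(list(frequencies.values()), dtype=float)
    _check_simplex(p)
    sum_sq = np.sum(p**2)
    sum_4 = np.sum(p**4)
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p_i^2)^2 - sum p_i^4
    return float(1.0 - sum_sq - (sum_sq**2 - sum_4))


def _check_simplex(p: np.ndarray) -> None:
    if p.size == 0 or np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("allele frequencies must be non-negative and sum to 1")


def observed_heterozygosity(matrix: GenotypeMatrix, marker: str) -> float:
    """Fraction of non-missing lines showing two distinct bands."""
    calls = [c for c in matrix.marker_calls(marker).values() if c is not None]
    if not calls:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    return sum(1 for c in calls if len(c) == 2) / len(calls)


def summarize_marker(matrix: GenotypeMatrix, marker: str) -> MarkerSummary:
    freqs = allele_frequencies(matrix, marker)
    return MarkerSummary(
        marker_id=marker,
        allele_count=len(freqs),
        major_allele_freq=max(freqs.values()),
        gene_diversity=gene_diversity(freqs),
        observed_heterozygosity=observed_heterozygosity(matrix, marker),
        pic=pic(freqs),
    )


def panel_summary(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker summaries plus a final arithmetic-mean row labelled 'mean'."""
    if not matrix.marker_ids:
        raise ValueError("matrix has no markers")
    rows = [summarize_marker(matrix, m) for m in matrix.marker_ids]
    df = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in rows],
            "allele_count": [r.allele_count for r in rows],
            "major_allele_freq": [r.major_allele_freq for r in rows],
            "gene_diversity": [r.gene_diversity for r in rows],
            "observed_heterozygosity": [r.observed_heterozygosity for r in rows],
            "pic": [r.pic for r in rows],
        }
    ).set_index("marker_id")
    df.loc["mean"] = df.mean(axis=0)
    return df


# ---------------------------------------------------------------------------
# Nei's minimum genetic distance
# ---------------------------------------------------------------------------

def _line_freqs(call) -> dict[int, float]:
    if len(call) == 1:
        (a,) = call
        return {a: 1.0}
    a, b = sorted(call)
    return {a: 0.5, b: 0.5}


def nei_minimum_distance(matrix: GenotypeMatrix, line_x: str, line_y: str) -> float:
    """Nei's minimum distance: mean over shared loci of (Jx + Jy)/2 - Jxy.

    J terms are sums over alleles of within-line frequency products; a
    heterozygote's alleles carry frequency 0.5 each.  Loci missing in either
    line are excluded; no shared locus is an error.
    """
    terms = []
    for marker in matrix.marker_ids:
        cx = matrix.get(line_x, marker)
        cy = matrix.get(line_y, marker)
        if cx is None or cy is None:
            continue
        fx = _line_freqs(cx)
        fy = _line_freqs(cy)
        jx = sum(v * v for v in fx.values())
        jy = sum(v * v for v in fy.values())
        jxy = sum(fx[a] * fy[a] for a in fx.keys() & fy.keys())
        terms.append((jx + jy) / 2.0 - jxy)
    if not terms:
        raise ValueError(f"lines {line_x!r} and {line_y!r} share no scored locus")
    return float(np.mean(terms))


def distance_matrix(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Symmetric Nei minimum distance matrix over all line pairs."""
    ids = matrix.line_ids
    d = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            val = nei_minimum_distance(matrix, x, y)
            d.at[x, y] = val
            d.at[y, x] = val
    return d


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(distances: pd.DataFrame) -> TreeNode:
    """UPGMA dendrogram of a symmetric distance matrix.

    Iteratively merges the closest pair of clusters; the new cluster's
    distance to any other is the size-weighted arithmetic average, and the
    merge node sits at height d/2, so the output is ultrametric.  Ties are
    broken by the lexicographically smallest pair of member-label tuples,
    making the tree invariant to input ordering.
    """
    ids = [str(i) for i in distances.index]
    if len(ids) < 2:
        raise ValueError("need at least two lines")
    mat = distances.to_numpy(dtype=float)
    if np.isnan(mat).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix is not symmetric")

    # cluster state: members (sorted leaf tuple), size, height, TreeNode
    clusters: dict[int, tuple[tuple[str, ...], int, float, TreeNode]] = {
        i: ((name,), 1, 0.0, TreeNode(name=name)) for i, name in enumerate(ids)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(mat[i, j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    }
    next_id = len(ids)
    while len(clusters) > 1:
        best = None
        for (i, j), d in dist.items():
            mi, mj = clusters[i][0], clusters[j][0]
            pair = (mi, mj) if mi < mj else (mj, mi)
            key = (d, pair)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        d = dist[(i, j)]
        members_i, size_i, height_i, node_i = clusters[i]
        members_j, size_j, height_j, node_j = clusters[j]
        height = d / 2.0
        node_i.length = height - height_i
        node_j.length = height - height_j
        parent = TreeNode(children=[node_i, node_j])
        members = tuple(sorted(members_i + members_j))
        for k in list(clusters):
            if k in (i, j):
                continue
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (
                size_i * d_ik + size_j * d_jk
            ) / (size_i + size_j)
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del clusters[i], clusters[j]
        clusters[next_id] = (members, size_i + size_j, height, parent)
        next_id += 1
    (_, _, _, root) = next(iter(clusters.values()))
    root.length = None
    return root


def leaf_depths(tree: TreeNode) -> dict[str, float]:
    """Root-to-tip path length per leaf (ultrametry check helper)."""
    return {tip.name: tip.accumulate_to_ancestor(tree) for tip in tree.tips()}


# ---------------------------------------------------------------------------
# 0/1 allele-presence coding
# ---------------------------------------------------------------------------

def binarize(matrix: GenotypeMatrix) -> pd.DataFrame:
    """0/1 presence matrix with one column per (marker, allele size) band.

    Column labels are "<marker>_<size>"; a heterozygote scores 1 in both of
    its marker's columns; missing calls yield pandas NA across the marker's
    columns.
    """
    columns = []
    data = {}
    for marker in matrix.marker_ids:
        alleles = sorted(
            {a for c in matrix.marker_calls(marker).values() if c is not None
             for a in c}
        )
        for allele in alleles:
            col = f"{marker}_{allele}"
            columns.append(col)
            vals = []
            for line in matrix.line_ids:
                call = matrix.get(line, marker)
                if call is None:
                    vals.append(pd.NA)
                else:
                    vals.append(1 if allele in call else 0)
            data[col] = vals
    return pd.DataFrame(data, index=pd.Index(matrix.line_ids, name="line_id"),
                        columns=columns).astype("Int64")


def debinarize(binary: pd.DataFrame) -> GenotypeMatrix:
    """Invert :func:`binarize` (column labels "<marker>_<size>")."""
    markers: dict[str, list[tuple[int, str]]] = {}
    for col in binary.columns:
        marker, _, size = str(col).rpartition("_")
        markers.setdefault(marker, []).append((int(size), col))
    calls = {}
    for line in binary.index:
        for marker, allele_cols in markers.items():
            present = set()
            missing = False
            for size, col in allele_cols:
                v = binary.at[line, col]
                if pd.isna(v):
                    missing = True
                    break
                if v:
                    present.add(size)
            calls[(str(line), marker)] = (
                None if missing or not present else frozenset(present)
            )
    return GenotypeMatrix(
        [str(i) for i in binary.index], list(markers), calls
    )
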