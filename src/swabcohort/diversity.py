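"""Alpha and beta diversity from first principles.

Alpha: Shannon entropy (natural log), inverse Simpson concentration, and
Faith's phylogenetic diversity in the root-inclusive ("PD whole tree")
convention. Beta: weighted UniFrac (raw and normalized) and classical
metric scaling (PCoA).

All metrics operate on rarefied counts; :func:`alpha_table` refuses
unrarefied input (unequal sample totals) unless explicitly overridden,
because unequal sequencing effort biases every one of these scores.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (DistanceMatrix, DiversityRecord, PhyloTree,
                         TaxonCountTable)


# ---------------------------------------------------------------------------
# abundance-only alpha metrics

def _proportions(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if x.size == 0 or np.any(x < 0):
        raise ValueError("counts must be non-negative and non-empty")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    return x / total


def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i over taxa with p_i > 0."""
    p = _proportions(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inverse_simpson(counts) -> float:
    """Inverse Simpson concentration 1 / sum p_i^2."""
    p = _proportions(counts)
    return float(1.0 / (p ** 2).sum())


# ---------------------------------------------------------------------------
# phylogenetic structure

class _BranchIndex:
    """Per-branch lengths and tip incidence for a rooted tree.

    One branch per node (the edge to its parent; the root edge has length
    0). ``incidence[b, t]`` is True when tip ``t`` descends through branch
    ``b``, so branch-level sample proportions are a single matrix product.
    """

    def __init__(self, tree: PhyloTree, taxon_ids: Sequence[str]) -> None:
        tree.validate_against_ids(taxon_ids)
        tip_pos = {t: i for i, t in enumerate(taxon_ids)}
        nodes = list(tree.tree.traverse(include_self=True))
        self.lengths = np.array([n.length for n in nodes], dtype=float)
        inc = np.zeros((len(nodes), len(taxon_ids)), dtype=bool)
        node_row = {id(n): i for i, n in enumerate(nodes)}
        # postorder accumulation: each node's tip set is the union of its
        # children's; tips outside taxon_ids are simply never marked.
        for node in tree.tree.postorder(include_self=True):
            row = node_row[id(node)]
            if node.is_tip():
                pos = tip_pos.get(node.name)
                if pos is not None:
                    inc[row, pos] = True
            else:
                for child in node.children:
                    inc[row] |= inc[node_row[id(child)]]
        self.incidence = inc

    def branch_fractions(self, proportions: np.ndarray) -> np.ndarray:
        """Fraction of a sample's sequences descending through each branch."""
        return self.incidence @ proportions


def _as_series(counts, taxon_ids=None) -> pd.Series:
    if isinstance(counts, pd.Series):
        return counts
    if isinstance(counts, Mapping):
        return pd.Series(counts, dtype=float)
    if taxon_ids is None:
        raise ValueError("taxon ids required for unlabeled count vectors")
    return pd.Series(np.asarray(counts, dtype=float), index=list(taxon_ids))


def faith_pd(present_taxa: Iterable[str], tree: PhyloTree) -> float:
    """Faith's PD: total branch length of the minimal subtree connecting
    the present tips and the root (root-inclusive convention)."""
    present = list(present_taxa)
    if not present:
        raise ValueError("faith_pd requires at least one present taxon")
    unknown = sorted(set(present) - tree.leaf_names)
    if unknown:
        raise ValueError(f"taxa not in tree: {unknown}")
    idx = _BranchIndex(tree, present)
    has_present = idx.incidence.any(axis=1)
    return float(idx.lengths[has_present].sum())


def weighted_unifrac(counts_a, counts_b, tree: PhyloTree,
                     normalized: bool = True,
                     taxon_ids: Sequence[str] | None = None) -> float:
    """Weighted UniFrac distance between two samples.

    Raw form: sum over branches of length × |P_A - P_B| where P_X is the
    fraction of sample X's sequences descending through the branch. The
    normalized form divides by sum of length × (P_A + P_B) and lies in
    [0, 1].
    """
    a = _as_series(counts_a, taxon_ids)
    b = _as_series(counts_b, taxon_ids)
    union = a.index.union(b.index)
    a = a.reindex(union, fill_value=0.0)
    b = b.reindex(union, fill_value=0.0)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("weighted UniFrac requires non-empty samples")
    idx = _BranchIndex(tree, list(union))
    pa = idx.branch_fractions((a / a.sum()).to_numpy())
    pb = idx.branch_fractions((b / b.sum()).to_numpy())
    raw = float((idx.lengths * np.abs(pa - pb)).sum())
    if not normalized:
        return raw
    denom = float((idx.lengths * (pa + pb)).sum())
    return raw / denom if denom > 0 else 0.0


def weighted_unifrac_matrix(table: TaxonCountTable, tree: PhyloTree,
                            normalized: bool = True) -> DistanceMatrix:
    """All-pairs weighted UniFrac over the samples of a count table."""
    tree.validate_against(table)
    idx = _BranchIndex(tree, table.taxon_ids)
    totals = table.sample_sums().to_numpy(dtype=float)
    if np.any(totals <= 0):
        raise ValueError("empty sample in table")
    props = table.counts.to_numpy(dtype=float) / totals
    branch = idx.incidence @ props          # n_branch x n_samples
    n = table.n_samples
    out = np.zeros((n, n))
    lengths = idx.lengths
    for i in range(n):
        diff = np.abs(branch[:, i:i + 1] - branch[:, i + 1:])
        num = lengths @ diff
        if normalized:
            denom = lengths @ (branch[:, i:i + 1] + branch[:, i + 1:])
            with np.errstate(invalid="ignore"):
                num = np.where(denom > 0, num / np.where(denom > 0, denom, 1),
                               0.0)
        out[i, i + 1:] = num
        out[i + 1:, i] = num
    return DistanceMatrix(table.sample_ids, out)


# ---------------------------------------------------------------------------
# ordination

def pcoa(dm: DistanceMatrix, k: int = 2):
    """Classical metric scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes the Gram matrix,
    and returns ``(coordinates, explained, eigenvalues)``: coordinates is a
    samples × axes DataFrame (axes ordered by decreasing eigenvalue),
    ``explained`` the fraction of positive-eigenvalue variance per
    returned axis, and ``eigenvalues`` the full spectrum (negative values
    reported, not silently dropped).
    """
    d2 = dm.data ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((gram + gram.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-10 * abs(eigval).max() if n else 0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; "
            f"returning {n_pos}", stacklevel=2)
        k = n_pos
    coords = eigvec[:, :k] * np.sqrt(eigval[:k]) if k else \
        np.zeros((n, 0))
    pos_sum = eigval[pos].sum()
    explained = (eigval[:k] / pos_sum) if pos_sum > 0 else np.zeros(k)
    frame = pd.DataFrame(coords, index=dm.sample_ids,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return frame, explained, eigval


# ---------------------------------------------------------------------------
# per-sample alpha table

def alpha_table(table: TaxonCountTable, tree: PhyloTree,
                allow_unrarefied: bool = False) -> list[DiversityRecord]:
    """One DiversityRecord per sample of a rarefied table.

    Refuses tables whose sample totals differ (not rarefied) unless
    ``allow_unrarefied`` is set.
    """
    totals = table.sample_sums()
    if not allow_unrarefied and totals.nunique() > 1:
        raise ValueError(
            "table does not look rarefied (unequal sample totals); pass "
            "allow_unrarefied=True to override")
    tree.validate_against(table)
    idx = _BranchIndex(tree, table.taxon_ids)
    records = []
    counts = table.counts
    for sid in table.sample_ids:
        col = counts[sid].to_numpy()
        present = col > 0
        pd_value = float(idx.lengths[idx.incidence[:, present].any(axis=1)]
                         .sum())
        records.append(DiversityRecord(
            sample_id=sid,
            shannon=shannon(col),
            inv_simpson=inverse_simpson(col),
            faith_pd=pd_value,
        ))
    return records


def alpha_frame(records: Sequence[DiversityRecord]) -> pd.DataFrame:
    """Tabular view of alpha records (sample_id index)."""
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "shannon": r.shannon,
          "inv_simpson": r.inv_simpson, "faith_pd": r.faith_pd}
         for r in records]).set_index("sample_id")
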