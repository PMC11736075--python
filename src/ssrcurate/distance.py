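"""Tolerance-aware Dice-Sorensen distance and molecular grouping.

The pairwise distance between two SSR profiles is

    d = 1 - 2 * sum(common alleles) / (sum(alleles sample1) + sum(alleles sample2))

summed over all panel markers, where an allele x of one profile counts as
common with an allele y of the other iff |x - y| <= tolerance (default 1 bp,
absorbing technical sizing variation).  Common alleles are counted as a
maximum one-to-one matching, not by transitive binning, so a 1 bp chain
(100, 101, 102) cannot inflate the count.  Markers null in both profiles
contribute nothing to either sum; a marker null in only one profile counts
that profile's alleles in the denominator only, penalizing dropout.

Profiles closer than the distance cutoff (default 0.25, i.e. at least 75%
identical) are linked, and the connected components of that graph — single
linkage — form the molecular groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model import MolecularGroup

log = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    """Both profiles are entirely null: the distance denominator is zero."""


@dataclass
class ClusterParams:
    """Tolerance for allele matching (bp) and the grouping distance cutoff."""

    tolerance_bp: int = 1
    cutoff: float = 0.25

    def __post_init__(self):
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must be in (0, 1)")
        if not (0 <= self.tolerance_bp <= 3):
            raise ValueError("tolerance_bp must be in [0, 3]")


@dataclass
class DistanceMatrix:
    sample_ids: list
    d: np.ndarray

    def __post_init__(self):
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample count")


def common_allele_count(a, b, tolerance_bp=1) -> int:
    """Size of a maximum one-to-one matching between AFL sets ``a`` and ``b``
    where x may match y iff |x - y| <= tolerance_bp.

    Computed greedily on the sorted sequences, which attains the brute-force
    maximum for interval tolerances: advancing past an unmatchable smaller
    value can never forgo a better pairing.
    """
    if not a or not b:
        return 0
    xs = sorted(a)
    ys = sorted(b)
    i = j = n = 0
    la, lb = len(xs), len(ys)
    while i < la and j < lb:
        d = xs[i] - ys[j]
        if d < -tolerance_bp:
            i += 1
        elif d > tolerance_bp:
            j += 1
        else:
            n += 1
            i += 1
            j += 1
    return n


def pairwise_distance(p1, p2, params=None) -> float:
    """Tolerance-aware Dice-Sorensen distance between two genotype profiles.

    Raises
    ------
    UndefinedDistanceError
        If both profiles are null at every marker.
    """
    params = params or ClusterParams()
    tol = params.tolerance_bp
    num = 0
    den = 0
    for marker, a in p1.items():
        b = p2.get(marker, frozenset())
        la, lb = len(a), len(b)
        if la == 0 and lb == 0:
            continue
        den += la + lb
        if la and lb:
            num += common_allele_count(a, b, tol)
    if den == 0:
        raise UndefinedDistanceError("both profiles are entirely null")
    return 1.0 - (2.0 * num) / den


def _profile_key(profile, markers):
    return tuple(tuple(sorted(profile[m])) for m in markers)


def _key_distance(u, v, tol) -> float:
    # Inlined hot loop over the per-marker sorted allele tuples of two
    # deduplicated profiles; identical calls short-circuit the matcher.
    num = 0
    den = 0
    for a, b in zip(u, v):
        la = len(a)
        lb = len(b)
        if not la and not lb:
            continue
        den += la + lb
        if la and lb:
            if a == b:
                num += la
            else:
                i = j = 0
                while i < la and j < lb:
                    d = a[i] - b[j]
                    if d < -tol:
                        i += 1
                    elif d > tol:
                        j += 1
                    else:
                        num += 1
                        i += 1
                        j += 1
    if den == 0:
        return 1.0  # flagged pair; caller warns
    return 1.0 - (2.0 * num) / den


def distance_matrix(samples, params=None) -> DistanceMatrix:
    """All-pairs distance matrix over the samples, in input order.

    Replicate samples with identical profiles are deduplicated before the
    quadratic pass, which makes genebank-sized inputs (thousands of samples,
    many replicates per cultivar) tractable.  Pairs where both profiles are
    entirely null have no defined distance; they are set to 1.0 with a
    warning rather than raising.
    """
    params = params or ClusterParams()
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    markers = list(samples[0].profile.keys())
    uniq = {}
    idx = []
    for s in samples:
        idx.append(uniq.setdefault(_profile_key(s.profile, markers), len(uniq)))
    keys = list(uniq)
    m = len(keys)
    tol = params.tolerance_bp

    all_null = [all(len(t) == 0 for t in k) for k in keys]
    if any(all_null):
        n_null = sum(all_null[i] for i in idx)
        log.warning(
            "%d sample(s) with entirely null profiles: their pairwise "
            "distances are undefined and flagged as 1.0",
            n_null,
        )

    du = np.zeros((m, m))
    for i in range(m):
        ki = keys[i]
        row = du[i]
        for j in range(i + 1, m):
            row[j] = _key_distance(ki, keys[j], tol)
    du += du.T

    d = du[np.ix_(idx, idx)]
    # All-null samples: undefined against everything, including identical
    # all-null replicates.
    null_samples = [si for si, ui in enumerate(idx) if all_null[ui]]
    if null_samples:
        d[null_samples, :] = 1.0
        d[:, null_samples] = 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(sample_ids=[s.sample_id for s in samples], d=d)


def cluster(dm: DistanceMatrix, params=None):
    """Partition samples into molecular groups by single linkage: connected
    components of the graph with an edge wherever d <= cutoff (inclusive).

    Groups are ordered by the first appearance (input order) of their
    earliest member; identifiers are not yet assigned.
    """
    params = params or ClusterParams()
    adj = dm.d <= params.cutoff
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    order = []
    members = {}
    for i, lab in enumerate(labels):
        if lab not in members:
            members[lab] = []
            order.append(lab)
        members[lab].append(dm.sample_ids[i])
    return [MolecularGroup(member_sample_ids=members[lab]) for lab in order]


def assign_group_ids(groups, start_index=1, width=4):
    """Assign sequential ``MD_####`` identifiers in group order.

    Zero-padded to ``width`` digits; indices beyond 10**width - 1 widen
    naturally (the 10000th group is ``MD_10000``).
    """
    out = []
    for offset, g in enumerate(groups):
        gid = f"MD_{start_index + offset:0{width}d}"
        out.append(MolecularGroup(member_sample_ids=list(g.member_sample_ids), group_id=gid))
    return out


def next_group_index(groups, width=4) -> int:
    """Smallest unused MD_#### index, for numbering groups created by splits."""
    mx = 0
    for g in groups:
        if g.group_id and g.group_id.startswith("MD_"):
            try:
                mx = max(mx, int(g.group_id[3:]))
            except ValueError:
                continue
    return mx + 1
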