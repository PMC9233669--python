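"""Greedy count-ranked Levenshtein clustering of selection-pool sequences.

Sequences are sorted by read count; the most abundant unassigned sequence
with count >= c_min seeds a family, and every unassigned sequence with
count >= a_min at Levenshtein distance strictly less than d_cutoff joins
it.  Assignment is permanent (a sequence never moves to a later family);
the scan repeats until no eligible center remains.  Defaults follow the
original selection-pool analysis: c_min = 10, a_min = 1, d_cutoff = 3,
n_min = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .sequence_space import levenshtein_distance


@dataclass
class FamilyCluster:
    """One greedy family: a center plus members within d_cutoff - 1 edits."""

    center: str
    members: list[str]  # includes the center, in count-rank order
    counts: dict[str, int]
    distances: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def _rank_order(pool: dict[str, int]) -> list[str]:
    # count descending, then lexicographic for determinism under ties
    return sorted(pool, key=lambda s: (-pool[s], s))


def cluster_pool(
    pool: dict[str, int] | pd.Series,
    c_min: int = 10,
    a_min: int = 1,
    d_cutoff: int = 3,
    n_min: int = 1,
) -> tuple[list[FamilyCluster], list[str]]:
    """Partition a sequence -> read-count pool into greedy families.

    Centers must have count >= c_min; members must have count >= a_min and
    Levenshtein distance < d_cutoff from their center.  Families smaller
    than n_min (counting the center) are dissolved back to unassigned.
    Sequences below a_min are skipped for the current family but remain
    available as members (or centers) later.

    Returns the family list in creation order plus the unassigned remainder.
    """
    if isinstance(pool, pd.Series):
        pool = {str(s): int(c) for s, c in pool.items()}
    if not pool:
        raise ValueError("pool is empty")
    if min(c_min, a_min, d_cutoff, n_min) < 1:
        raise ValueError("clustering parameters must be positive")

    order = _rank_order(pool)
    unassigned = set(order)
    families: list[FamilyCluster] = []
    for center in order:
        if center not in unassigned or pool[center] < c_min:
            continue
        members, dists = [], {}
        for seq in order:
            if seq not in unassigned or pool[seq] < a_min:
                continue
            d = levenshtein_distance(center, seq)
            if d < d_cutoff:
                members.append(seq)
                dists[seq] = d
        if len(members) < n_min:
            continue
        unassigned.difference_update(members)
        families.append(
            FamilyCluster(
                center=center,
                members=members,
                counts={s: pool[s] for s in members},
                distances=dists,
            )
        )
    leftovers = [s for s in order if s in unassigned]
    return families, leftovers


def families_table(families: list[FamilyCluster]) -> pd.DataFrame:
    """Long-form table: family_id, center, member, count, distance_to_center."""
    rows = [
        {
            "family_id": i + 1,
            "center": fam.center,
            "member": seq,
            "count": fam.counts[seq],
            "distance_to_center": fam.distances[seq],
        }
        for i, fam in enumerate(families)
        for seq in fam.members
    ]
    return pd.DataFrame(
        rows, columns=["family_id", "center", "member", "count", "distance_to_center"]
    )


def compare_clusterings(
    a: list[FamilyCluster], b: list[FamilyCluster]
) -> pd.DataFrame:
    """Best-match member overlap between two clusterings.

    For each family in ``a``, finds the family in ``b`` with the largest
    Jaccard member overlap.  The returned table carries one row per family
    of ``a`` (center, best-matching center in ``b``, overlap fraction,
    whether the centers coincide) plus an ``agreement`` column holding the
    member-weighted mean overlap (1 for identical clusterings, 0 for
    disjoint ones).
    """
    rows = []
    b_sets = [(fam.center, set(fam.members)) for fam in b]
    total_members = sum(fam.size for fam in a)
    weighted = 0.0
    for fam in a:
        sa = set(fam.members)
        best_center, best_jaccard = None, 0.0
        for center_b, sb in b_sets:
            jac = len(sa & sb) / len(sa | sb) if sa | sb else 0.0
            if jac > best_jaccard:
                best_center, best_jaccard = center_b, jac
        weighted += best_jaccard * fam.size
        rows.append({
            "center_a": fam.center,
            "best_center_b": best_center,
            "overlap": best_jaccard,
            "same_center": best_center == fam.center,
        })
    agreement = weighted / total_members if total_members else 0.0
    out = pd.DataFrame(rows, columns=["center_a", "best_center_b", "overlap", "same_center"])
    out["agreement"] = agreement
    return out
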