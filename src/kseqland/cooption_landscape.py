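"""Co-option census and fitness-landscape connectivity.

A sequence is "active" on a substrate when its catalytic enhancement
exceeds the threshold r_t (default 5, chosen so that active sequences sit
clearly above the 95% background band); activity on two or more substrates
marks co-option potential.  The landscape analysis asks whether the
per-substrate fitness peaks of a family can reach one another through
single-substitution steps while maintaining substantial overall activity
(sum of r over substrates above a floor, default 30 = r_t x 6 substrates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .sequence_space import hamming_distance

DEFAULT_ACTIVITY_THRESHOLD = 5.0
DEFAULT_ACTIVITY_FLOOR = 30.0


def count_active_substrates(
    r: pd.Series | np.ndarray, r_t: float = DEFAULT_ACTIVITY_THRESHOLD
) -> int:
    """Number of substrates with enhancement strictly above r_t."""
    r = np.asarray(r, dtype=float)
    return int(np.sum(r > r_t))


@dataclass
class CooptionCensus:
    """Distribution of per-sequence active-substrate counts in one family."""

    counts: pd.Series  # index 0..N substrates -> number of sequences
    fractions: pd.Series
    n_sequences: int
    n_cooptable: int  # active on >= 2 substrates
    r_t: float


def cooption_census(
    enhancement: pd.DataFrame, r_t: float = DEFAULT_ACTIVITY_THRESHOLD
) -> CooptionCensus:
    """Census of how many substrates each sequence is active on."""
    if enhancement.empty:
        raise ValueError("enhancement table is empty")
    n_sub = enhancement.shape[1]
    active = (enhancement.to_numpy(dtype=float) > r_t).sum(axis=1)
    counts = pd.Series(
        np.bincount(active, minlength=n_sub + 1), index=range(n_sub + 1), name="count"
    )
    return CooptionCensus(
        counts=counts,
        fractions=counts / len(enhancement),
        n_sequences=len(enhancement),
        n_cooptable=int((active >= 2).sum()),
        r_t=r_t,
    )


def select_peak_set(
    enhancement: pd.DataFrame,
    wild_type: str,
    top_n: int = 6,
) -> tuple[list[str], dict[str, str]]:
    """Wild type plus the ``top_n`` highest-enhancement sequences per substrate.

    Ranking ties are broken by higher total activity, then lexicographically
    by sequence, so the selection is deterministic.  Returns the seed node
    list (sorted) and the single most active sequence per substrate.
    """
    total = enhancement.sum(axis=1)
    seeds: set[str] = {wild_type} if wild_type in enhancement.index else set()
    if wild_type not in enhancement.index:
        raise ValueError("wild-type sequence missing from the enhancement table")
    peaks: dict[str, str] = {}
    for substrate in enhancement.columns:
        order = (
            pd.DataFrame({
                "r": enhancement[substrate],
                "total": total,
                "seq": enhancement.index,
            })
            .sort_values(["r", "total", "seq"], ascending=[False, False, True])
        )
        ranked = order["seq"].tolist()
        seeds.update(ranked[:top_n])
        peaks[substrate] = ranked[0]
    return sorted(seeds), peaks


def intervening_candidates(a: str, b: str) -> list[str]:
    """The two single-substitution hybrids between sequences at Hamming d = 2."""
    diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if len(diff) != 2:
        raise ValueError("candidates exist only for pairs at Hamming distance 2")
    i, j = diff
    h1 = a[:j] + b[j] + a[j + 1 :]  # a with b's base at j
    h2 = a[:i] + b[i] + a[i + 1 :]  # a with b's base at i
    return [h1, h2]


def find_intervening(
    seeds: Iterable[str],
    enhancement: pd.DataFrame,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> list[str]:
    """Connectors between seed pairs at Hamming distance 2.

    For every seed pair at d = 2, the two hybrid sequences at d = 1 to both
    are looked up in the family table; those with total enhancement above
    ``activity_floor`` are returned (single pass over seed pairs only).
    """
    total = enhancement.sum(axis=1)
    seeds = sorted(set(seeds))
    found: set[str] = set()
    for a, b in combinations(seeds, 2):
        if len(a) != len(b) or hamming_distance(a, b) != 2:
            continue
        for cand in intervening_candidates(a, b):
            if cand in total.index and total[cand] > activity_floor and cand not in seeds:
                found.add(cand)
    return sorted(found)


@dataclass
class LandscapeGraph:
    """Hamming-adjacency graph over the selected high-activity sequences."""

    graph: nx.Graph
    peaks: dict[str, str]  # substrate -> most active sequence
    wild_type: str
    activity_floor: float


def build_landscape_graph(
    enhancement: pd.DataFrame,
    wild_type: str,
    top_n: int = 6,
    activity_floor: float = DEFAULT_ACTIVITY_FLOOR,
) -> LandscapeGraph:
    """Assemble the evolutionary-pathway graph for one family.

    Nodes are the wild type, the per-substrate top performers, and
    qualifying intervening sequences; edges join nodes at Hamming distance
    1.  Node attributes carry each sequence's enhancement vector, total
    activity, and peak/wild-type flags.
    """
    seeds, peaks = select_peak_set(enhancement, wild_type, top_n=top_n)
    connectors = find_intervening(seeds, enhancement, activity_floor)
    nodes = sorted(set(seeds) | set(connectors))
    G = nx.Graph()
    total = enhancement.sum(axis=1)
    peak_of = {}
    for sub, seq in peaks.items():
        peak_of.setdefault(seq, []).append(sub)
    for seq in nodes:
        G.add_node(
            seq,
            r=enhancement.loc[seq].to_dict(),
            total_activity=float(total[seq]),
            is_wild_type=(seq == wild_type),
            is_connector=(seq in connectors),
            peak_for=peak_of.get(seq, []),
        )
    for a, b in combinations(nodes, 2):
        if len(a) == len(b) and hamming_distance(a, b) == 1:
            G.add_edge(a, b)
    return LandscapeGraph(G, peaks, wild_type, activity_floor)


@dataclass
class ConnectivityReport:
    """Component structure of a landscape graph and peak accessibility."""

    components: list[set[str]]
    peaks_connected: bool
    peak_path_lengths: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.components)


def connectivity_report(landscape: LandscapeGraph) -> ConnectivityReport:
    """Connected components and pairwise path lengths between substrate peaks.

    ``peaks_connected`` is True when every substrate's top sequence lies in
    one component, i.e. each peak can reach the others through single
    mutations within the retained high-activity set.  Unreachable peak
    pairs get infinite path length.
    """
    G = landscape.graph
    components = [set(c) for c in nx.connected_components(G)]
    peak_seqs = sorted(set(landscape.peaks.values()))
    comp_of = {}
    for i, comp in enumerate(components):
        for node in comp:
            comp_of[node] = i
    peaks_connected = len({comp_of[p] for p in peak_seqs}) <= 1
    lengths: dict[tuple[str, str], float] = {}
    for a, b in combinations(peak_seqs, 2):
        if comp_of[a] == comp_of[b]:
            lengths[(a, b)] = float(nx.shortest_path_length(G, a, b))
        else:
            lengths[(a, b)] = float("inf")
    return ConnectivityReport(components, peaks_connected, lengths)


def census_table(
    enhancement: pd.DataFrame,
    family: pd.Series,
    r_t: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> pd.DataFrame:
    """Per-family co-option census in long form (family, n_active, count, fraction)."""
    rows = []
    for fam, idx in enhancement.groupby(family).groups.items():
        census = cooption_census(enhancement.loc[idx], r_t=r_t)
        for n_active, count in census.counts.items():
            rows.append({
                "family": fam, "n_active_substrates": n_active,
                "count": int(count), "fraction": float(census.fractions[n_active]),
                "n_cooptable": census.n_cooptable,
            })
    return pd.DataFrame(rows)
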