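"""Genealogical-tree fate analysis.

During early biofilm growth under flow, every division on the surface
produces two daughters, each of which either stays attached or detaches
("leaves").  Divisions therefore fall into three exclusive categories —
both daughters stay, exactly one stays, both leave — and the per-category
probabilities summarise how a strain partitions its offspring between the
surface-bound and mobile phases.

A :class:`LineageForest` holds the reconstructed trees; divisions whose
daughters were observed too briefly to call are censored and excluded from
the denominator ``n_div``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .errors import StructuralError

FATES = ("stay", "leave", "censored")


@dataclass
class LineageNode:
    """One cell in a genealogical tree.

    ``fate`` describes the cell's own terminal outcome: ``"stay"`` if it
    remained attached to the end of the observation (or until it divided),
    ``"leave"`` if it detached, ``"censored"`` if it was observed too
    briefly to decide.  Dividing cells carry ``t_division``.
    """

    id: str
    parent: Optional[str]
    t_birth: float
    t_division: Optional[float] = None
    fate: str = "stay"

    def __post_init__(self):
        if self.fate not in FATES:
            raise StructuralError(f"unknown fate {self.fate!r} for node {self.id}")
        if self.t_division is not None and self.t_division <= self.t_birth:
            raise StructuralError(
                f"node {self.id}: t_division {self.t_division} <= t_birth {self.t_birth}"
            )

    def outcome(self) -> str:
        """Postdivision outcome of this cell as a daughter: a cell that
        itself divided necessarily stayed on the surface."""
        if self.t_division is not None:
            return "stay"
        return self.fate


@dataclass
class LineageForest:
    """A set of genealogical trees indexed by node id."""

    nodes: Dict[str, LineageNode] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise StructuralError(
                    f"node {node.id} references missing parent {node.parent}"
                )
        # cycle check by walking to the root from every node
        for node in self.nodes.values():
            seen = {node.id}
            cur = node
            while cur.parent is not None:
                if cur.parent in seen:
                    raise StructuralError(f"parent cycle through node {cur.parent}")
                seen.add(cur.parent)
                cur = self.nodes[cur.parent]

    @property
    def roots(self) -> List[str]:
        return [n.id for n in self.nodes.values() if n.parent is None]

    def children(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {nid: [] for nid in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                out[node.parent].append(node.id)
        return out

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class FateCounts:
    """Counts of classified postdivision fate categories.

    ``n_div`` counts only divisions with two decidable daughters; divisions
    with a censored daughter are tallied in ``n_censored``.
    """

    n_both_stay: int
    n_one_stays: int
    n_both_leave: int
    n_censored: int = 0

    def __post_init__(self):
        for v in (self.n_both_stay, self.n_one_stays, self.n_both_leave, self.n_censored):
            if v < 0:
                raise StructuralError("fate counts must be nonnegative")

    @property
    def n_div(self) -> int:
        return self.n_both_stay + self.n_one_stays + self.n_both_leave


@dataclass
class FateEstimate:
    """Estimated fate probabilities with two uncertainty conventions.

    ``err_literal`` is the historical 1/n_div convention used alongside
    published fate bar charts; ``err_binomial`` is the per-category binomial
    standard error sqrt(p(1-p)/n_div), the one to use for inference.
    When no division could be classified (``n_div == 0``) the probabilities
    are absent and ``flag`` explains why.
    """

    n_div: int
    p_both_stay: Optional[float] = None
    p_one_stays: Optional[float] = None
    p_both_leave: Optional[float] = None
    err_literal: Optional[float] = None
    err_binomial: Optional[Dict[str, float]] = None
    flag: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "p_both_stay": self.p_both_stay,
            "p_one_stays": self.p_one_stays,
            "p_both_leave": self.p_both_leave,
            "n_div": self.n_div,
            "err_paper": self.err_literal,
            "err_binomial": self.err_binomial,
            "flag": self.flag,
        }


def classify_fates(forest: LineageForest) -> FateCounts:
    """Partition every division of *forest* into the three fate categories.

    A division contributes to ``n_div`` only if both daughters have a
    decidable outcome; if either daughter is censored the division is
    counted in ``n_censored`` instead.  A division node with a number of
    daughters other than two is a structural error.
    """
    children = forest.children()
    bad = [
        nid
        for nid, node in forest.nodes.items()
        if node.t_division is not None and len(children[nid]) != 2
    ]
    if bad:
        raise StructuralError(f"division nodes without exactly two daughters: {sorted(bad)}")

    n_bs = n_os = n_bl = n_cens = 0
    for nid, node in forest.nodes.items():
        if node.t_division is None:
            continue
        d1, d2 = (forest.nodes[c] for c in children[nid])
        o1, o2 = d1.outcome(), d2.outcome()
        if "censored" in (o1, o2):
            n_cens += 1
        elif o1 == "stay" and o2 == "stay":
            n_bs += 1
        elif o1 == "leave" and o2 == "leave":
            n_bl += 1
        else:
            n_os += 1
    return FateCounts(n_bs, n_os, n_bl, n_cens)


def fate_probabilities(counts: FateCounts) -> FateEstimate:
    """Estimate per-category fate probabilities from classified counts.

    Probabilities are category counts over ``n_div`` and sum to one.  Both
    uncertainty conventions are reported (see :class:`FateEstimate`).
    """
    n = counts.n_div
    if n == 0:
        return FateEstimate(n_div=0, flag="no classified divisions (n_div = 0)")
    ps = {
        "both_stay": counts.n_both_stay / n,
        "one_stays": counts.n_one_stays / n,
        "both_leave": counts.n_both_leave / n,
    }
    return FateEstimate(
        n_div=n,
        p_both_stay=ps["both_stay"],
        p_one_stays=ps["one_stays"],
        p_both_leave=ps["both_leave"],
        err_literal=1.0 / n,
        err_binomial={k: math.sqrt(p * (1.0 - p) / n) for k, p in ps.items()},
    )
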