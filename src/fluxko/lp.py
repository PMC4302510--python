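"""FindPath: the LP feasibility oracle over the steady-state flux cone.

Every lattice computation in this package reduces to one question: *is
there a steady-state flux vector that uses reaction t while avoiding the
knocked-out reactions K?*  For the flux cone this is decided by the linear
programs

    max { +/- v_t  |  S v = 0,  v_Irr >= 0,  v_k = 0 for k in K }

The cone is unbounded, so a box ``-M <= v <= M`` (``0 <= v <= M`` for
irreversible reactions) is imposed; supports are scale-invariant, hence the
support of a bounded optimizer still witnesses membership in the support
lattice.  Two tolerances are kept apart: a *decision* tolerance for "the
target carries flux" (a missed nonzero target corrupts results) and a
smaller *support extraction* tolerance (a spurious support member is
harmless - any feasible support is a lattice element).

The rest of the package talks to this module only through
``find_path(target, knockouts)``; swapping in a different pathway notion
(e.g. thermodynamically feasible supports) means swapping this oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = ["Pathway", "LPConfig", "OracleError", "ConeModel", "verify_support"]


class OracleError(RuntimeError):
    """Numerical failure inside the LP solver (distinct from 'no pathway')."""


@dataclass(frozen=True)
class Pathway:
    """Support of a feasible steady-state flux vector (a lattice element)."""

    support: frozenset[str]
    witness_values: Mapping[str, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "support", frozenset(self.support))


@dataclass(frozen=True)
class LPConfig:
    """Numerical settings for the feasibility oracle.

    ``zero_tolerance`` trims the optimizer when extracting supports;
    ``decision_tolerance`` decides whether the target reaction carries
    flux; ``big_m`` is the box bound replacing the unbounded cone.
    """

    zero_tolerance: float = 1e-9
    decision_tolerance: float = 1e-6
    big_m: float = 1000.0
    honor_bounds: bool = False
    solver: str = "highs"

    def __post_init__(self):
        if not (0.0 < self.zero_tolerance < 1.0):
            raise ValueError("zero_tolerance must lie in (0, 1)")
        if not (0.0 < self.decision_tolerance < 1.0):
            raise ValueError("decision_tolerance must lie in (0, 1)")
        if self.big_m < 1.0:
            raise ValueError("big_m must be at least 1")
        if self.solver != "highs":
            raise ValueError(f"unknown solver backend {self.solver!r}")


class ConeModel:
    """The steady-state flux-cone model of a network, with an LP FindPath.

    Instances cache the stoichiometric matrix and per-reaction boxes and
    count every LP solved in :attr:`lp_calls` (the diagnostic the runtime
    tables of a knockout simulation are built from).
    """

    def __init__(self, net: MetabolicNetwork, config: LPConfig | None = None):
        self.net = net
        self.config = config or LPConfig()
        self.reactions = net.reactions
        self.lp_calls = 0
        self._ridx = net.reaction_index()
        self._A = net.stoich_matrix()
        self._b = np.zeros(len(net.metabolites))
        M = self.config.big_m
        lower = np.empty(len(net.reactions))
        upper = np.empty(len(net.reactions))
        for i, r in enumerate(net.reactions):
            lb = 0.0 if r in net.irreversible else -M
            ub = M
            if self.config.honor_bounds and net.bounds and r in net.bounds:
                blo, bhi = net.bounds[r]
                lb = max(lb, blo) if np.isfinite(blo) else lb
                ub = min(ub, bhi) if np.isfinite(bhi) else ub
            lower[i], upper[i] = lb, ub
        self._lower, self._upper = lower, upper

    # -- core oracle ------------------------------------------------------

    def _solve(self, c: np.ndarray, lower: np.ndarray, upper: np.ndarray):
        self.lp_calls += 1
        res = linprog(
            c,
            A_eq=self._A,
            b_eq=self._b,
            bounds=np.column_stack([lower, upper]),
            method="highs",
        )
        if res.status != 0:
            raise OracleError(
                f"LP solver failure (status {res.status}): {res.message}"
            )
        return res

    def find_path(
        self, target: str, knockouts=frozenset()
    ) -> Pathway | None:
        """Support of a flux vector using ``target`` and avoiding ``knockouts``.

        Maximizes ``v_target`` (and, for reversible targets, minimizes it if
        the maximum is zero); returns ``None`` when the target is blocked in
        the sub-cone, i.e. no steady-state pathway avoiding the knockout set
        can carry flux through it.
        """
        K = self.net.check_knockout_set(knockouts)
        if target not in self._ridx:
            raise ValueError(f"unknown target reaction {target!r}")
        if target in K:
            raise ValueError(f"target {target!r} is in the knockout set")
        lower, upper = self._lower.copy(), self._upper.copy()
        for k in K:
            i = self._ridx[k]
            lower[i] = upper[i] = 0.0
        t = self._ridx[target]
        eps = self.config.decision_tolerance
        c = np.zeros(len(self.reactions))

        c[t] = -1.0  # maximize v_t
        res = self._solve(c, lower, upper)
        if -res.fun > eps:
            return self._extract(res.x, K)
        if lower[t] < 0.0:  # reversible target: try the backward direction
            c[t] = 1.0
            res = self._solve(c, lower, upper)
            if res.fun < -eps:
                return self._extract(res.x, K)
        return None

    def _extract(self, v: np.ndarray, knockouts: frozenset[str]) -> Pathway:
        tol = self.config.zero_tolerance
        support = set()
        values = {}
        for r, i in self._ridx.items():
            if abs(v[i]) > tol and r not in knockouts:
                support.add(r)
                values[r] = float(v[i])
        return Pathway(frozenset(support), values)


def verify_support(
    net_or_model: MetabolicNetwork | ConeModel,
    support,
    config: LPConfig | None = None,
) -> bool:
    """Check that ``support`` is itself the support of some flux vector.

    Decided by computing the maximal support achievable inside the sub-cone
    ``{v | v_i = 0 for i not in support}``: the candidate belongs to the
    support lattice iff that maximum equals the candidate exactly.  The
    empty set is always valid (v = 0).
    """
    model = (
        net_or_model
        if isinstance(net_or_model, ConeModel)
        else ConeModel(net_or_model, config)
    )
    support = frozenset(support)
    unknown = support - set(model.reactions)
    if unknown:
        raise ValueError(f"unknown reactions in support: {sorted(unknown)}")
    outside = frozenset(model.reactions) - support
    covered: set[str] = set()
    for t in sorted(support):
        if t in covered:
            continue
        path = model.find_path(t, outside)
        if path is None:
            return False
        covered |= path.support
    return covered == support
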