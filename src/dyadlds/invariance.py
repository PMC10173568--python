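"""Measurement-invariance ladder across reporters with partial-invariance rescue.

The ladder runs configural -> metric -> scalar, sharing loading then
intercept parameters across the two reporters.  A step is accepted when the
loss of fit versus the last accepted step satisfies both delta criteria
(default: CFI loss <= 0.010 and RMSEA increase <= 0.015).  When a step
fails, a capped partial-invariance search frees the equality-constrained
measurement parameter with the largest modification index, at most two per
parameter class, before declaring non-invariance.

Two reporter layouts are supported: ``joint`` keeps both reporters' items in
one model with correlated factors (respecting the within-dyad dependence the
difference-score model needs) and ``two-group`` treats the reporters as
independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments import item_columns, subscale_definition, scored_item_frame
from .sem import (
    ModelSpec,
    GroupData,
    fit_ml,
    chisq_diff,
    Candidate,
    modification_indices,
    FitResult,
    ParameterTable,
    DiffResult,
)

MARKER_POS = 0  # first item of each subscale anchors loading=1, intercept=0
DEFAULT_CRITERIA = {"cfi": 0.010, "rmsea": 0.015}


class LadderError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# spec builders
# ---------------------------------------------------------------------------


def _load_label(construct: str, pos: int) -> str:
    return f"l_{construct}_{pos}"


def _int_label(construct: str, pos: int) -> str:
    return f"n_{construct}_{pos}"


def joint_cfa_spec(
    construct: str,
    loading_eq: frozenset[int] | set[int] = frozenset(),
    intercept_eq: frozenset[int] | set[int] = frozenset(),
    residual_cov: bool = False,
) -> ModelSpec:
    """One-sample two-factor CFA over both reporters' items.

    ``loading_eq`` / ``intercept_eq`` list the non-marker item positions
    (1-4) whose measurement parameter is constrained equal across reporters.
    """
    self_cols = item_columns(construct, "self")
    parent_cols = item_columns(construct, "parent")
    spec = ModelSpec(self_cols + parent_cols, ["fS", "fP"])
    for reporter, cols, factor in (("self", self_cols, "fS"), ("parent", parent_cols, "fP")):
        for pos, col in enumerate(cols):
            if pos == MARKER_POS:
                spec.add("lambda", col, factor, free=False, value=1.0)
                spec.add("nu", col, free=False, value=0.0)
            else:
                lab_l = _load_label(construct, pos) if (
                    reporter == "self" or pos in loading_eq) else None
                lab_n = _int_label(construct, pos) if (
                    reporter == "self" or pos in intercept_eq) else None
                spec.add("lambda", col, factor, free=True, value=1.0, label=lab_l)
                spec.add("nu", col, free=True, value=0.0, label=lab_n)
            spec.add("theta", col, col, free=True, value=0.3)
    if residual_cov:
        for s_col, p_col in zip(self_cols, parent_cols):
            spec.add("theta", s_col, p_col, free=True, value=0.0)
    spec.add("psi", "fS", "fS", free=True, value=0.3)
    spec.add("psi", "fP", "fP", free=True, value=0.3)
    spec.add("psi", "fS", "fP", free=True, value=0.1)
    spec.add("alpha", "fS", free=True, value=0.3)
    spec.add("alpha", "fP", free=True, value=0.3)
    return spec


def single_reporter_cfa_spec(construct: str, reporter: str, share=frozenset(),
                             share_intercepts=frozenset()) -> ModelSpec:
    """Single-factor CFA over one reporter's five items (group-mode building
    block; shared labels implement cross-group equality)."""
    cols = item_columns(construct, reporter)
    spec = ModelSpec(cols, ["f"])
    for pos, col in enumerate(cols):
        if pos == MARKER_POS:
            spec.add("lambda", col, "f", free=False, value=1.0)
            spec.add("nu", col, free=False, value=0.0)
        else:
            spec.add("lambda", col, "f", free=True, value=1.0,
                     label=_load_label(construct, pos) if pos in share else None)
            spec.add("nu", col, free=True, value=0.0,
                     label=_int_label(construct, pos) if pos in share_intercepts else None)
        spec.add("theta", col, col, free=True, value=0.3)
    spec.add("psi", "f", "f", free=True, value=0.3)
    spec.add("alpha", "f", free=True, value=0.3)
    return spec


def build_ladder(construct: str, mode: str = "joint", residual_cov: bool = False):
    """Ordered (name, builder) pairs; each builder maps the current equality
    sets to model spec(s) for its step."""
    nonmarker = frozenset(range(1, 5))
    if mode == "joint":
        def make(l_eq, n_eq):
            return joint_cfa_spec(construct, l_eq, n_eq, residual_cov)
    elif mode == "two-group":
        def make(l_eq, n_eq):
            self_spec = single_reporter_cfa_spec(construct, "self", nonmarker, nonmarker)
            # relabel self side so only the shared positions carry shared labels
            parent_spec = single_reporter_cfa_spec(construct, "parent", l_eq, n_eq)
            return [self_spec, parent_spec]
    else:
        raise LadderError(f"unknown mode {mode!r}")
    return make


# ---------------------------------------------------------------------------
# report structures
# ---------------------------------------------------------------------------


@dataclass
class LadderStep:
    name: str
    fit: FitResult
    table: ParameterTable
    deltas: DiffResult | None
    accepted: bool
    freed_loadings: list[int] = field(default_factory=list)
    freed_intercepts: list[int] = field(default_factory=list)


@dataclass
class InvarianceReport:
    construct: str
    mode: str
    steps: list[LadderStep]
    accepted_step: str | None
    invariant: bool
    criteria: dict
    freed_loadings: list[int] = field(default_factory=list)  # item ids
    freed_intercepts: list[int] = field(default_factory=list)

    def step(self, name: str) -> LadderStep:
        for s in self.steps:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            rows.append({
                "construct": self.construct, "model": s.name,
                "chisq": s.fit.stat, "df": s.fit.df,
                "CFI": s.fit.cfi, "RMSEA": s.fit.rmsea, "SRMR": s.fit.srmr,
                "dCFI": s.deltas.d_cfi if s.deltas else np.nan,
                "dRMSEA": s.deltas.d_rmsea if s.deltas else np.nan,
                "dSRMR": s.deltas.d_srmr if s.deltas else np.nan,
                "accepted": s.accepted,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the ladder
# ---------------------------------------------------------------------------


def _prepare_data(frame: pd.DataFrame, construct: str, mode: str, weights):
    """Scored item data in the layout each mode expects."""
    self_block = scored_item_frame(frame, construct, "self")
    parent_block = scored_item_frame(frame, construct, "parent")
    if isinstance(weights, str):
        w = frame[weights].to_numpy(dtype=float)
    elif weights is None:
        w = np.ones(len(frame))
    else:
        w = np.asarray(weights, dtype=float)
    if mode == "joint":
        data = pd.concat([self_block, parent_block], axis=1)
        keep = ~data.isna().any(axis=1) & ~np.isnan(w)
        gd = GroupData(data[keep].to_numpy(dtype=float), w[keep], list(data.columns))
        return [gd]
    # two-group: reporters as independent samples
    out = []
    for block in (self_block, parent_block):
        keep = ~block.isna().any(axis=1) & ~np.isnan(w)
        out.append(GroupData(block[keep].to_numpy(dtype=float), w[keep], list(block.columns)))
    return out


def _passes(deltas: DiffResult, criteria: dict) -> bool:
    return deltas.d_cfi <= criteria["cfi"] and deltas.d_rmsea <= criteria["rmsea"]


def _fit_step(make, l_eq, n_eq, data, seed):
    specs = make(frozenset(l_eq), frozenset(n_eq))
    spec_list = specs if isinstance(specs, list) else [specs]
    table, fit = fit_ml(spec_list, data, mode="moments", seed=seed, compute_se=False)
    return spec_list, table, fit


def partial_search(
    make,
    data,
    parameter_class: str,
    eq_set: set[int],
    other_eq: tuple[set[int], set[int]],
    last_accepted_fit: FitResult,
    criteria: dict,
    max_free: int = 2,
    seed: int = 0,
):
    """Free the largest-MI equality-constrained parameter, refit, re-evaluate.

    ``parameter_class`` is 'loading' or 'intercept'; ``eq_set`` is mutated
    copy-wise.  Stops at acceptance or the cap.  Ties (MI within 1e-10) break
    by item order.  Returns (eq_set, freed_positions, step_fits) where
    step_fits holds each refit (spec_list, table, fit, deltas).
    """
    l_eq, n_eq = other_eq
    freed: list[int] = []
    fits = []
    current = set(eq_set)
    while len(freed) < max_free and current:
        specs = make(frozenset(current if parameter_class == "loading" else l_eq),
                     frozenset(current if parameter_class == "intercept" else n_eq))
        spec_list = specs if isinstance(specs, list) else [specs]
        table, _ = fit_ml(spec_list, data, mode="moments", seed=seed, compute_se=False)
        cands = []
        parent_group = 0 if len(spec_list) == 1 else 1
        parent_cols = spec_list[parent_group].observed
        for pos in sorted(current):
            col = parent_cols[5 + pos] if len(spec_list) == 1 else parent_cols[pos]
            if parameter_class == "loading":
                factor = "fP" if len(spec_list) == 1 else "f"
                cands.append(Candidate(parent_group, "lambda", col, factor, "unshare"))
            else:
                cands.append(Candidate(parent_group, "nu", col, None, "unshare"))
        mis = modification_indices(spec_list, table, data, cands)
        if not mis:
            break
        # largest MI; ties break by item order (first candidate wins)
        mi_by_row = {m.candidate.row: m.mi for m in mis}
        best_cand = None
        best_mi = -np.inf
        for c in cands:
            mi = mi_by_row.get(c.row, -np.inf)
            if mi > best_mi + 1e-10:
                best_cand, best_mi = c, mi
        if best_cand is None:
            break
        pos = sorted(current)[[c.row for c in cands].index(best_cand.row)]
        current.discard(pos)
        freed.append(pos)
        new_l = frozenset(current) if parameter_class == "loading" else frozenset(l_eq)
        new_n = frozenset(current) if parameter_class == "intercept" else frozenset(n_eq)
        specs = make(new_l, new_n)
        spec_list = specs if isinstance(specs, list) else [specs]
        table, fit = fit_ml(spec_list, data, mode="moments", seed=seed, compute_se=False)
        deltas = chisq_diff(fit, last_accepted_fit)
        fits.append((spec_list, table, fit, deltas))
        if _passes(deltas, criteria):
            break
    return current, freed, fits


def run_ladder(
    frame: pd.DataFrame,
    construct: str,
    weights=None,
    mode: str = "joint",
    criteria: dict | None = None,
    max_free: int = 2,
    residual_cov: bool = False,
    seed: int = 0,
) -> InvarianceReport:
    """Full configural -> metric -> scalar sequence with partial rescue."""
    criteria = dict(DEFAULT_CRITERIA if criteria is None else criteria)
    make = build_ladder(construct, mode, residual_cov)
    data = _prepare_data(frame, construct, mode, weights)
    definition = subscale_definition(construct, "self")
    nonmarker = set(range(1, 5))
    steps: list[LadderStep] = []

    _, conf_table, conf_fit = _fit_step(make, set(), set(), data, seed)
    if not conf_fit.converged:
        raise LadderError(f"{construct}: configural model did not converge")
    steps.append(LadderStep("configural", conf_fit, conf_table, None, True))
    last_accepted = conf_fit

    # ---- metric ----------------------------------------------------------
    l_eq = set(nonmarker)
    n_eq: set[int] = set()
    freed_loadings: list[int] = []
    _, m_table, m_fit = _fit_step(make, l_eq, n_eq, data, seed)
    m_deltas = chisq_diff(m_fit, last_accepted)
    metric_ok = _passes(m_deltas, criteria)
    steps.append(LadderStep("metric", m_fit, m_table, m_deltas, metric_ok))
    if metric_ok:
        last_accepted = m_fit
    else:
        l_eq, freed_loadings, rescue = partial_search(
            make, data, "loading", l_eq, (l_eq, n_eq), last_accepted,
            criteria, max_free, seed,
        )
        if rescue:
            _, p_table, p_fit, p_deltas = rescue[-1]
            ok = _passes(p_deltas, criteria)
            steps.append(LadderStep(
                "metric-partial", p_fit, p_table, p_deltas, ok,
                freed_loadings=list(freed_loadings),
            ))
            if ok:
                last_accepted = p_fit
                metric_ok = True
    if not metric_ok:
        return _finish(construct, mode, steps, None, criteria,
                       freed_loadings, [], definition)

    # ---- scalar ----------------------------------------------------------
    n_eq = set(nonmarker)
    freed_intercepts: list[int] = []
    _, s_table, s_fit = _fit_step(make, l_eq, n_eq, data, seed)
    s_deltas = chisq_diff(s_fit, last_accepted)
    scalar_ok = _passes(s_deltas, criteria)
    steps.append(LadderStep("scalar", s_fit, s_table, s_deltas, scalar_ok,
                            freed_loadings=list(freed_loadings)))
    accepted = "scalar" if scalar_ok else None
    if not scalar_ok:
        n_eq, freed_intercepts, rescue = partial_search(
            make, data, "intercept", n_eq, (l_eq, n_eq), last_accepted,
            criteria, max_free, seed,
        )
        if rescue:
            _, p_table, p_fit, p_deltas = rescue[-1]
            ok = _passes(p_deltas, criteria)
            steps.append(LadderStep(
                "scalar-partial", p_fit, p_table, p_deltas, ok,
                freed_loadings=list(freed_loadings),
                freed_intercepts=list(freed_intercepts),
            ))
            if ok:
                accepted = "scalar-partial"
    return _finish(construct, mode, steps, accepted, criteria,
                   freed_loadings, freed_intercepts, definition)


def _finish(construct, mode, steps, accepted, criteria,
            freed_loadings, freed_intercepts, definition) -> InvarianceReport:
    item_ids = definition.item_ids
    return InvarianceReport(
        construct=construct, mode=mode, steps=steps,
        accepted_step=accepted, invariant=accepted is not None,
        criteria=criteria,
        freed_loadings=[item_ids[p] for p in freed_loadings],
        freed_intercepts=[item_ids[p] for p in freed_intercepts],
    )


def accepted_equality_sets(report: InvarianceReport) -> tuple[frozenset[int], frozenset[int]]:
    """Positions still constrained equal in the accepted model."""
    if not report.invariant:
        raise LadderError(f"{report.construct}: no accepted invariance model")
    definition = subscale_definition(report.construct, "self")
    pos_of = {item: i for i, item in enumerate(definition.item_ids)}
    nonmarker = set(range(1, 5))
    l_eq = nonmarker - {pos_of[i] for i in report.freed_loadings}
    n_eq = nonmarker - {pos_of[i] for i in report.freed_intercepts}
    return frozenset(l_eq), frozenset(n_eq)
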