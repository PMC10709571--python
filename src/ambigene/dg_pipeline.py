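"""The difficult-gene detection pipeline.

A *difficult gene* (DG) is one whose counts are significant, after
Benjamini-Hochberg adjustment, for BOTH the mapper factor and the group
factor of the additive two-factor NB GLM fitted to the stacked
multi-aligner table — its measured expression depends materially on which
aligner produced the counts.

The central objects follow the Model/Results convention:

>>> model = DifficultGeneModel.from_tables(tables, design)
>>> res = model.fit(alpha=0.05)
>>> res.calls            # per-gene p-values, DG flags, ranks
>>> res.summary()        # per-mapper percentage table

``find_dgs`` / ``rank_dgs`` / ``call_degs_per_mapper`` / ``summarize`` are
the equivalent functional entry points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_design import CountTable, DesignTable, StackedCounts, stack_mappers
from .normalization import NormFactors, filter_low_expression, tmm_factors
from .nbglm import (DesignMatrix, bh_adjust, build_design, build_oneway_design,
                    estimate_dispersion, lrt_factor, nb_exact_test)

__all__ = [
    "DifficultGeneModel",
    "DGResults",
    "DGCallSet",
    "DGSummary",
    "find_dgs",
    "rank_dgs",
    "call_degs_per_mapper",
    "summarize",
]

DEFAULT_ALPHA = 0.05


@dataclass
class DGCallSet:
    """Joint-significance DG calls plus per-mapper DEG calls.

    ``calls`` has one row per kept gene with columns ``padj_mapper``,
    ``padj_group``, ``p_mapper``, ``p_group``, ``is_dg`` and ``rank``; ``deg``
    maps mapper id to a frame with ``p_value``, ``p_adjusted``, ``is_deg``.
    """

    calls: pd.DataFrame
    deg: dict[str, pd.DataFrame]
    alpha: float
    n_kept: int

    @property
    def dg_genes(self) -> list[str]:
        return self.calls.index[self.calls["is_dg"]].tolist()

    def deg_genes(self, mapper: str) -> list[str]:
        d = self.deg[mapper]
        return d.index[d["is_deg"]].tolist()


@dataclass
class DGSummary:
    """Per-mapper percentages of difficult genes (a Table-2-style summary)."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.2f}")


def rank_dgs(callset: DGCallSet | pd.DataFrame) -> list[str]:
    """Order genes by (padj_mapper asc, padj_group asc, gene_id asc).

    Genes most significant for the mapper factor come first; ties on the
    mapper adjustment are broken by the group adjustment, then by gene id.
    """
    calls = callset.calls if isinstance(callset, DGCallSet) else callset
    df = calls.reset_index().rename(columns={"index": "gene_id"})
    df = df.sort_values(["padj_mapper", "padj_group", "gene_id"],
                        kind="mergesort")
    return df["gene_id"].tolist()


def call_degs_per_mapper(table: CountTable, design: DesignTable,
                         alpha: float = DEFAULT_ALPHA, min_count: int = 5,
                         max_low_fraction: float = 0.30,
                         prior_df: float = 10.0) -> pd.DataFrame:
    """Differentially expressed genes for one mapper's counts alone.

    The table is filtered and TMM-normalized independently (a standard
    single-aligner workflow).  Two groups are compared with the NB exact
    test; more than two with a one-way NB GLM likelihood-ratio test.  The
    returned frame is indexed by kept gene id with columns ``p_value``,
    ``p_adjusted``, ``is_deg``.
    """
    filtered, kept, _ = filter_low_expression(table, min_count,
                                              max_low_fraction)
    if not kept:
        return pd.DataFrame(columns=["p_value", "p_adjusted", "is_deg"])
    norm = tmm_factors(filtered)
    eff = norm.effective_sizes
    groups = np.array([design.group_of(s) for s in filtered.sample_ids])
    levels = sorted(set(groups.tolist()))
    X = build_oneway_design(groups)
    disp, _ = estimate_dispersion(filtered.counts, X, np.log(eff),
                                  prior_df=prior_df)
    if len(levels) == 2:
        in_a = groups == levels[0]
        p = nb_exact_test(filtered.counts[:, in_a],
                          filtered.counts[:, ~in_a], disp,
                          eff[in_a], eff[~in_a])
    else:
        X0 = DesignMatrix(np.ones((len(groups), 1)), ["intercept"])
        res = lrt_factor(filtered.counts, X, X0, np.log(eff), disp,
                         gene_ids=kept, factor="group")
        p = res.p_value
    padj = bh_adjust(p)
    return pd.DataFrame({"p_value": p, "p_adjusted": padj,
                         "is_deg": padj < alpha},
                        index=pd.Index(kept, name="gene_id"))


class DifficultGeneModel:
    """Two-factor (group + mapper) NB GLM over stacked aligner count tables.

    Construction runs the deterministic preprocessing: stack the per-mapper
    tables, drop low-expression genes (count < ``min_count`` in more than
    ``max_low_fraction`` of the columns), and compute TMM effective library
    sizes.  :meth:`fit` estimates dispersions, runs the two likelihood-ratio
    tests and calls DGs.
    """

    def __init__(self, stacked: StackedCounts, *, min_count: int = 5,
                 max_low_fraction: float = 0.30):
        self.raw = stacked
        self.min_count = min_count
        self.max_low_fraction = max_low_fraction
        self.stacked, self.kept_genes, self.dropped_genes = \
            filter_low_expression(stacked, min_count, max_low_fraction)
        self.norm: NormFactors | None = None
        if self.kept_genes:
            self.norm = tmm_factors(self.stacked)
        self.design_matrix: DesignMatrix = build_design(stacked)

    @classmethod
    def from_tables(cls, tables: Mapping[str, CountTable],
                    design: DesignTable, **kwargs) -> "DifficultGeneModel":
        return cls(stack_mappers(tables, design), **kwargs)

    @property
    def offsets(self) -> np.ndarray:
        assert self.norm is not None
        return np.log(self.norm.effective_sizes)

    def fit(self, alpha: float = DEFAULT_ALPHA, prior_df: float = 10.0,
            use_adjusted: bool = True, call_degs: bool = True) -> "DGResults":
        """Estimate dispersions, test both factors and call DGs.

        ``use_adjusted=False`` switches the joint-significance call to raw
        p-values.  ``call_degs`` additionally runs the per-mapper DEG
        analysis (NB exact test / one-way LRT on each aligner's own table).
        """
        if not self.kept_genes:
            calls = pd.DataFrame(columns=["p_mapper", "padj_mapper", "p_group",
                                          "padj_group", "is_dg", "rank"])
            return DGResults(self, DGCallSet(calls, {}, alpha, 0), None, None,
                             np.array([]), float("nan"))
        X_full = self.design_matrix
        X_no_mapper = X_full.drop_factor("mapper")
        X_no_group = X_full.drop_factor("group")
        disp, common = estimate_dispersion(self.stacked, X_full, self.offsets,
                                           prior_df=prior_df)
        res_mapper = lrt_factor(self.stacked, X_full, X_no_mapper,
                                self.offsets, disp, factor="mapper")
        res_group = lrt_factor(self.stacked, X_full, X_no_group,
                               self.offsets, disp, factor="group")
        pm = res_mapper.p_adjusted if use_adjusted else res_mapper.p_value
        pg = res_group.p_adjusted if use_adjusted else res_group.p_value
        is_dg = (pm < alpha) & (pg < alpha)
        calls = pd.DataFrame({
            "p_mapper": res_mapper.p_value,
            "padj_mapper": res_mapper.p_adjusted,
            "p_group": res_group.p_value,
            "padj_group": res_group.p_adjusted,
            "is_dg": is_dg,
        }, index=pd.Index(self.kept_genes, name="gene_id"))
        order = rank_dgs(calls)
        calls["rank"] = pd.Series(range(1, len(order) + 1), index=order)
        deg: dict[str, pd.DataFrame] = {}
        if call_degs:
            from .io_design import unstack
            tables, design = unstack(self.raw)
            for m in self.raw.mappers:
                deg[m] = call_degs_per_mapper(
                    tables[m], design, alpha=alpha, min_count=self.min_count,
                    max_low_fraction=self.max_low_fraction,
                    prior_df=prior_df)
        callset = DGCallSet(calls, deg, alpha, len(self.kept_genes))
        return DGResults(self, callset, res_mapper, res_group, disp, common)


@dataclass
class DGResults:
    """Fitted difficult-gene analysis: calls, test tables and dispersions."""

    model: DifficultGeneModel
    callset: DGCallSet
    mapper_test: object
    group_test: object
    dispersions: np.ndarray
    common_dispersion: float

    @property
    def calls(self) -> pd.DataFrame:
        return self.callset.calls

    @property
    def dg_genes(self) -> list[str]:
        return self.callset.dg_genes

    @property
    def ranked_genes(self) -> list[str]:
        return rank_dgs(self.callset)

    def summary(self) -> DGSummary:
        return summarize(self.callset)

    def summary_text(self) -> str:
        lines = [
            "Difficult-gene analysis",
            f"  kept genes:        {self.callset.n_kept}",
            f"  dropped genes:     {len(self.model.dropped_genes)}",
            f"  mappers:           {', '.join(self.model.raw.mappers)}",
            f"  common dispersion: {self.common_dispersion:.4g}",
            f"  alpha:             {self.callset.alpha}",
            f"  difficult genes:   {len(self.dg_genes)}",
        ]
        if self.callset.deg:
            summ = summarize(self.callset)
            lines.append("")
            lines.append(str(summ))
        return "\n".join(lines)


def find_dgs(tables: Mapping[str, CountTable], design: DesignTable,
             alpha: float = DEFAULT_ALPHA, *, min_count: int = 5,
             max_low_fraction: float = 0.30, prior_df: float = 10.0,
             use_adjusted: bool = True, call_degs: bool = True) -> DGResults:
    """Run the full five-step DG procedure.

    stack -> filter -> TMM -> dispersion -> dual LRT -> BH -> joint call,
    plus (by default) the per-mapper DEG analysis.  Deterministic given its
    inputs.  Requires at least two mappers over identical sample/gene sets.
    """
    if len(tables) < 2:
        raise ValueError("difficult-gene calling needs >= 2 mappers")
    model = DifficultGeneModel.from_tables(tables, design,
                                           min_count=min_count,
                                           max_low_fraction=max_low_fraction)
    return model.fit(alpha=alpha, prior_df=prior_df,
                     use_adjusted=use_adjusted, call_degs=call_degs)


def summarize(callset: DGCallSet) -> DGSummary:
    """Per-mapper DG percentages.

    For mapper m, with DG_m = DG intersect DEG_m:
      pct_dg_of_all = 100 * |DG_m| / G_kept  (G_kept from the stacked filter)
      pct_dg_of_deg = 100 * |DG_m| / |DEG_m|   (NA when no DEGs)
    The unconditioned 100 * |DG| / G_kept is exposed as ``pct_dg_total``.
    """
    dg = set(callset.dg_genes)
    G = callset.n_kept
    rows = []
    for m, d in callset.deg.items():
        deg_m = set(d.index[d["is_deg"]])
        dg_m = dg & deg_m
        rows.append({
            "mapper": m,
            "n_kept": G,
            "n_dg": len(dg),
            "n_deg": len(deg_m),
            "n_dg_and_deg": len(dg_m),
            "pct_dg_of_all": 100.0 * len(dg_m) / G if G else 0.0,
            "pct_dg_of_deg": (100.0 * len(dg_m) / len(deg_m)
                              if deg_m else float("nan")),
            "pct_dg_total": 100.0 * len(dg) / G if G else 0.0,
        })
    return DGSummary(pd.DataFrame(rows).set_index("mapper")
                     if rows else pd.DataFrame())
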