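"""Gene-structure and biotype features from a GTF annotation.

Difficult genes tend to be structurally simple (few exons, single
transcript) and are enriched for pseudogenes, whose sequence similarity to
parent genes confuses aligners.  This module computes per-gene exon/
transcript statistics and biotype flags, and the DG vs non-DG median
profile used to characterize a call set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd

__all__ = ["GeneFeatures", "gene_features", "group_feature_medians"]

NUMERIC_FEATURES = ["ex_min", "ex_max", "ex_median", "tr_length", "ex_no",
                    "tr_no"]


@dataclass
class GeneFeatures:
    """Transcript-median structural statistics for one gene.

    Exon lengths use 1-based inclusive GTF coordinates (end - start + 1);
    transcript length is the mature length (sum of exon lengths).  Gene-level
    values are medians across the gene's transcripts.
    """

    gene_id: str
    ex_min: float
    ex_max: float
    ex_median: float
    tr_length: float
    genomic_span: float
    ex_no: float
    tr_no: int
    biotype: str
    is_pseudogene: bool
    is_coding: bool


def _build_db(gtf: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(str(gtf), ":memory:", force=True,
                              keep_order=True, merge_strategy="warning",
                              disable_infer_genes=True,
                              disable_infer_transcripts=True)


def gene_features(gtf: str | Path, gene_ids: Iterable[str] | None = None):
    """Structural features per gene from an Ensembl-dialect GTF.

    Returns ``(features, missing)``: a DataFrame indexed by gene id and the
    list of requested ids absent from the annotation.  Strand is ignored for
    length computations; an exon with end < start is a hard error.
    """
    db = _build_db(gtf)
    biotypes: dict[str, str] = {}
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        biotypes[gid] = gene.attributes.get("gene_biotype", [""])[0]
    # exons grouped per transcript per gene
    per_gene: dict[str, dict[str, list[int]]] = {}
    for ex in db.features_of_type("exon"):
        if ex.end < ex.start:
            raise ValueError(
                f"exon with end < start for gene "
                f"{ex.attributes.get('gene_id', ['?'])[0]!r}")
        gid = ex.attributes.get("gene_id", ["?"])[0]
        tid = ex.attributes.get("transcript_id", ["?"])[0]
        per_gene.setdefault(gid, {}).setdefault(tid, []).append(
            ex.end - ex.start + 1)
        if gid not in biotypes:
            bt = ex.attributes.get("gene_biotype", [""])
            biotypes[gid] = bt[0]
    spans: dict[str, tuple[int, int]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes.get("gene_id", ["?"])[0]
        lo, hi = spans.get(gid, (ex.start, ex.end))
        spans[gid] = (min(lo, ex.start), max(hi, ex.end))

    wanted = list(gene_ids) if gene_ids is not None else sorted(per_gene)
    missing = [g for g in wanted if g not in per_gene]
    rows = []
    for gid in wanted:
        if gid not in per_gene:
            continue
        tx = per_gene[gid]
        ex_mins, ex_maxs, ex_meds, tr_lens, ex_nos = [], [], [], [], []
        for lengths in tx.values():
            arr = np.asarray(lengths, dtype=float)
            ex_mins.append(arr.min())
            ex_maxs.append(arr.max())
            ex_meds.append(float(np.median(arr)))
            tr_lens.append(float(arr.sum()))
            ex_nos.append(float(len(arr)))
        bt = biotypes.get(gid, "")
        lo, hi = spans[gid]
        rows.append({
            "gene_id": gid,
            "ex_min": float(np.median(ex_mins)),
            "ex_max": float(np.median(ex_maxs)),
            "ex_median": float(np.median(ex_meds)),
            "tr_length": float(np.median(tr_lens)),
            "genomic_span": float(hi - lo + 1),
            "ex_no": float(np.median(ex_nos)),
            "tr_no": len(tx),
            "biotype": bt,
            "is_pseudogene": "pseudogene" in bt,
            "is_coding": bt == "protein_coding",
        })
    features = pd.DataFrame(rows).set_index("gene_id") if rows else \
        pd.DataFrame(columns=NUMERIC_FEATURES + ["genomic_span", "biotype",
                                                 "is_pseudogene", "is_coding"])
    return features, missing


def group_feature_medians(features: pd.DataFrame,
                          dg_flags: Mapping[str, bool] | pd.Series
                          ) -> pd.DataFrame:
    """Median feature profile for the DG group vs the non-DG group.

    ``dg_flags`` maps gene id -> bool over the genes to profile (typically
    the DEG set).  Numeric features are medians within each group; biotype
    shares are integer-rounded percentages.  An empty group yields an NA row.
    """
    flags = pd.Series(dict(dg_flags)) if not isinstance(dg_flags, pd.Series) \
        else dg_flags
    out = []
    for label, want in (("DG", True), ("non-DG", False)):
        ids = [g for g, v in flags.items() if bool(v) == want
               and g in features.index]
        if not ids:
            row = {f: float("nan") for f in NUMERIC_FEATURES}
            row.update({"pct_pseudogene": float("nan"),
                        "pct_coding": float("nan"), "n_genes": 0})
        else:
            sub = features.loc[ids]
            row = {f: float(sub[f].median()) for f in NUMERIC_FEATURES}
            row["pct_pseudogene"] = int(round(
                100.0 * sub["is_pseudogene"].mean()))
            row["pct_coding"] = int(round(100.0 * sub["is_coding"].mean()))
            row["n_genes"] = len(ids)
        row["type"] = label
        out.append(row)
    return pd.DataFrame(out).set_index("type")
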