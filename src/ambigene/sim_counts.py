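"""Synthetic multi-aligner RNA-seq counts with planted ground truth.

The generator reads the difficult-gene model forward: counts are negative
binomial with

    log2(mu) = log2(N_column) + b_g + group effect + mapper effect

where ``b_g`` is a gene baseline, group effects are additive shifts attached
to one non-reference group, and mapper effects — mimicking an aligner that
systematically over- or under-counts a subset of genes (e.g. pseudogene-like
genes) — are attached to one non-reference mapper.  Genes carrying both a
group and a mapper effect are the planted difficult genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_design import CountTable, DesignTable

__all__ = ["SimConfig", "SimTruth", "simulate"]


@dataclass
class SimConfig:
    """Generator settings.

    ``n_per_group`` samples in each of ``n_groups`` groups observed by
    ``k_mappers`` aligners.  Baseline gene abundances are log2-uniform on
    ``baseline_log2_range``; per-column library-size factors are log-uniform
    on ``lib_size_range``.  ``frac_group_de`` / ``frac_mapper_dg`` /
    ``frac_joint`` are disjoint gene fractions carrying a group effect only,
    a mapper effect only, or both (the planted difficult genes).  Effect
    signs are random with equal probability.
    """

    n_genes: int = 2000
    n_per_group: int = 5
    n_groups: int = 2
    k_mappers: int = 3
    baseline_log2_range: tuple[float, float] = (3.0, 10.0)
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    frac_group_de: float = 0.0
    frac_mapper_dg: float = 0.0
    frac_joint: float = 0.0
    log2fc_group: float = 2.0
    log2fc_mapper: float = 2.0
    mapper_names: tuple[str, ...] = ()
    group_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_group_de", "frac_mapper_dg", "frac_joint"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_group_de + self.frac_mapper_dg + self.frac_joint > 1.0:
            raise ValueError("effect fractions sum above 1")
        if min(self.n_genes, self.n_per_group) < 1 or self.n_groups < 2 \
                or self.k_mappers < 1:
            raise ValueError("all sizes must be positive (>= 2 groups)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not self.mapper_names:
            defaults = ("hisat2", "star", "subread")
            self.mapper_names = tuple(
                defaults[i] if i < 3 else f"mapper{i+1}"
                for i in range(self.k_mappers))
        if not self.group_names:
            self.group_names = tuple(chr(ord("A") + i)
                                     for i in range(self.n_groups))
        if len(self.mapper_names) != self.k_mappers:
            raise ValueError("mapper_names length != k_mappers")
        if len(self.group_names) != self.n_groups:
            raise ValueError("group_names length != n_groups")


@dataclass
class SimTruth:
    """Per-gene ground truth: baselines, effect sizes and labels."""

    gene_ids: list[str]
    baseline_log2: np.ndarray
    group_effect_log2: np.ndarray  # shift applied to the affected group
    mapper_effect_log2: np.ndarray  # shift applied to the affected mapper
    dispersion: np.ndarray
    labels: np.ndarray  # {null, group-only, mapper-only, joint}
    affected_group: str = ""
    affected_mapper: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "baseline_log2": self.baseline_log2,
            "group_effect_log2": self.group_effect_log2,
            "mapper_effect_log2": self.mapper_effect_log2,
            "dispersion": self.dispersion,
            "label": self.labels,
        })

    @property
    def joint_genes(self) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == "joint"]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray,
             phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) sample; phi = 0 falls back to Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi == 0
    if pois.any():
        out[pois] = rng.poisson(np.broadcast_to(mu, mu.shape)[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        m = mu[~pois]
        out[~pois] = rng.negative_binomial(r, r / (r + m))
    return out


def simulate(config: SimConfig):
    """Draw per-mapper count tables, a design table and the ground truth.

    Returns ``(tables, design, truth)`` where ``tables`` maps mapper name to
    :class:`CountTable`.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    n = config.n_per_group * config.n_groups
    k = config.k_mappers

    gene_ids = [f"gene{i+1:05d}" for i in range(G)]
    sample_ids = []
    groups = []
    for gi, gname in enumerate(config.group_names):
        for j in range(config.n_per_group):
            sample_ids.append(f"s{gi * config.n_per_group + j + 1:03d}")
            groups.append(gname)
    design = DesignTable(sample_ids, groups)

    baseline = rng.uniform(*config.baseline_log2_range, size=G)
    phi = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (G,))
    phi = np.array(phi)

    n_joint = int(round(config.frac_joint * G))
    n_gonly = int(round(config.frac_group_de * G))
    n_monly = int(round(config.frac_mapper_dg * G))
    perm = rng.permutation(G)
    joint_idx = perm[:n_joint]
    gonly_idx = perm[n_joint:n_joint + n_gonly]
    monly_idx = perm[n_joint + n_gonly:n_joint + n_gonly + n_monly]

    labels = np.full(G, "null", dtype=object)
    labels[joint_idx] = "joint"
    labels[gonly_idx] = "group-only"
    labels[monly_idx] = "mapper-only"

    sign = lambda size: rng.choice([-1.0, 1.0], size=size)
    group_eff = np.zeros(G)
    mapper_eff = np.zeros(G)
    g_hit = np.concatenate([joint_idx, gonly_idx]).astype(int)
    m_hit = np.concatenate([joint_idx, monly_idx]).astype(int)
    group_eff[g_hit] = config.log2fc_group * sign(len(g_hit))
    mapper_eff[m_hit] = config.log2fc_mapper * sign(len(m_hit))

    # effects land on the last (non-reference) group / mapper
    affected_group = config.group_names[-1]
    affected_mapper = config.mapper_names[-1]
    group_mask = np.array([g == affected_group for g in groups], dtype=float)

    lo, hi = np.log(config.lib_size_range[0]), np.log(config.lib_size_range[1])
    lib = np.exp(rng.uniform(lo, hi, size=(k, n)))  # per (mapper, sample)

    tables: dict[str, CountTable] = {}
    ln2 = np.log(2.0)
    for mi, mname in enumerate(config.mapper_names):
        map_mask = 1.0 if mname == affected_mapper else 0.0
        log2mu = (baseline[:, None]
                  + group_eff[:, None] * group_mask[None, :]
                  + mapper_eff[:, None] * map_mask
                  + np.log(lib[mi])[None, :] / ln2)
        mu = np.exp(ln2 * log2mu)
        counts = _nb_draw(rng, mu, np.broadcast_to(phi[:, None], mu.shape))
        tables[mname] = CountTable(list(gene_ids), list(sample_ids), counts)

    truth = SimTruth(gene_ids, baseline, group_eff, mapper_eff, phi.copy(),
                     labels, affected_group, affected_mapper)
    return tables, design, truth
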