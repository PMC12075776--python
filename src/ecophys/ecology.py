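"""Ecology summaries on externally produced mapping and genome tables.

The inputs here come from standard pipelines (competitive read recruitment,
fastANI, CheckM); this module owns only the downstream arithmetic:

* RPKM normalization of sample x genome mapped-read counts — reads per
  kilobase of genome per million recruited read base pairs;
* species-level subcluster abundance as exact per-sample sums of member
  genome RPKMs;
* ANI-threshold clustering: symmetrize the pairwise identity matrix, draw
  an edge wherever identity reaches the species boundary (95% by default),
  and take connected components;
* the genome quality score used for dereplication representative choice,
  completeness - 5 x contamination;
* Spearman rank correlation of subcluster abundance with an environmental
  variable (e.g. temperature), pairwise-complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ANIMatrixError,
    EmptyInputError,
    InsufficientSamplesError,
    RecruitmentTableError,
)

__all__ = [
    "RecruitmentTable",
    "RPKMTable",
    "ClusterAssignment",
    "compute_rpkm",
    "subcluster_abundance",
    "ani_clusters",
    "genome_quality",
    "env_abundance_correlation",
]


@dataclass
class RecruitmentTable:
    """Mapped-read counts per genome (rows) and sample (columns).

    ``recruited_bp`` is the per-sample total base pairs of recruited reads
    (the competitive-recruitment denominator); ``total_bp`` optionally
    carries the total sequenced base pairs per sample for the alternative
    normalization. ``sample_metadata`` rows are indexed by sample id.
    """

    counts: pd.DataFrame
    genome_lengths: pd.Series
    recruited_bp: pd.Series
    total_bp: pd.Series | None = None
    sample_metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.values < 0).any():
            raise RecruitmentTableError("counts must be nonnegative")
        missing = set(self.counts.index) - set(self.genome_lengths.index)
        if missing:
            raise RecruitmentTableError(f"genomes without lengths: {sorted(missing)}")
        self.genome_lengths = self.genome_lengths.loc[self.counts.index].astype(float)
        if (self.genome_lengths <= 0).any():
            raise RecruitmentTableError("genome lengths must be > 0")
        missing = set(self.counts.columns) - set(self.recruited_bp.index)
        if missing:
            raise RecruitmentTableError(f"samples without recruited_bp: {sorted(missing)}")
        self.recruited_bp = self.recruited_bp.loc[self.counts.columns].astype(float)
        has_counts = self.counts.sum(axis=0) > 0
        if ((self.recruited_bp <= 0) & has_counts).any():
            raise RecruitmentTableError(
                "recruited_bp must be positive wherever a sample has counts"
            )


@dataclass
class RPKMTable:
    """Normalized abundances with per-genome summaries and ranking."""

    values: pd.DataFrame  # genomes x samples
    genome_summary: pd.DataFrame  # median/q1/q3 per genome
    ranking: pd.Index  # genomes ordered by descending median RPKM
    denominator: str = "recruited"

    def top_genomes(self, n: int = 5) -> pd.Index:
        return self.ranking[:n]


@dataclass
class ClusterAssignment:
    """Genome -> cluster partition with within/between ANI statistics."""

    labels: pd.Series  # genome -> cluster id
    threshold: float
    within_stats: pd.DataFrame  # per cluster: n, min/median within-ANI
    between_min: float
    between_max: float
    symmetrize: str = "mean"
    clusters: dict[int, tuple[str, ...]] = field(default_factory=dict)


def compute_rpkm(
    t: RecruitmentTable, denominator: Literal["recruited", "total"] = "recruited"
) -> RPKMTable:
    """RPKM[g, s] = counts[g, s] / (length_g / 1e3) / (bp_s / 1e6).

    The per-sample denominator defaults to recruited read base pairs; the
    ``total`` option divides by total sequenced base pairs instead. Samples
    with zero denominator and zero counts yield all-zero RPKM.
    """
    if denominator == "recruited":
        bp = t.recruited_bp
    elif denominator == "total":
        if t.total_bp is None:
            raise RecruitmentTableError("total_bp not provided")
        bp = t.total_bp.loc[t.counts.columns].astype(float)
    else:
        raise ValueError("denominator must be 'recruited' or 'total'")
    per_kb = t.genome_lengths / 1e3
    per_million = bp / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = t.counts.div(per_kb, axis=0).div(per_million, axis=1)
    vals = vals.where(t.counts != 0, 0.0)  # exact zeros where no reads mapped
    med = vals.median(axis=1)
    summary = pd.DataFrame(
        {
            "median": med,
            "q1": vals.quantile(0.25, axis=1),
            "q3": vals.quantile(0.75, axis=1),
        }
    )
    ranking = med.sort_values(ascending=False, kind="mergesort").index
    return RPKMTable(
        values=vals, genome_summary=summary, ranking=ranking, denominator=denominator
    )


def subcluster_abundance(
    r: RPKMTable, membership: Mapping[str, str]
) -> pd.DataFrame:
    """Sum member-genome RPKMs per subcluster and sample.

    Genomes absent from ``membership`` are excluded with a warning. Returns
    a subcluster x sample DataFrame; the per-subcluster median across
    samples is available as ``result.median(axis=1)``.
    """
    if not membership:
        raise EmptyInputError("empty subcluster membership")
    assigned = [g for g in r.values.index if g in membership]
    unassigned = [g for g in r.values.index if g not in membership]
    if unassigned:
        warnings.warn(
            f"{len(unassigned)} genome(s) without subcluster assignment "
            f"excluded: {unassigned}",
            stacklevel=2,
        )
    if not assigned:
        raise EmptyInputError("membership covers none of the genomes")
    groups = pd.Series({g: membership[g] for g in assigned}, name="subcluster")
    return r.values.loc[assigned].groupby(groups).sum()


def _validate_ani(m: pd.DataFrame) -> pd.DataFrame:
    m = m.astype(float)
    if m.shape[0] != m.shape[1]:
        raise ANIMatrixError("ANI matrix must be square")
    if list(m.index) != list(m.columns):
        raise ANIMatrixError("row and column genome labels must match")
    vals = m.values
    if np.any(vals < 0) or np.any(vals > 100):
        raise ANIMatrixError("ANI values must lie in [0, 100]")
    if not np.allclose(np.diag(vals), 100.0):
        raise ANIMatrixError("self-identity must be 100")
    return m


def ani_clusters(
    m: pd.DataFrame,
    threshold: float = 95.0,
    symmetrize: Literal["mean", "min"] = "mean",
) -> ClusterAssignment:
    """Species-level clusters from a pairwise ANI matrix.

    Possibly asymmetric directed values are symmetrized (arithmetic mean by
    default, elementwise min by flag), an undirected edge is drawn for every
    pair at or above the threshold, and clusters are the connected
    components (single linkage — the threshold applies to edges, so a
    cluster's within-ANI minimum may fall below it and is reported as a
    statistic). Cluster ids are assigned in order of each cluster's
    alphabetically first genome.
    """
    m = _validate_ani(m)
    vals = m.values
    if symmetrize == "mean":
        sym = (vals + vals.T) / 2.0
    elif symmetrize == "min":
        sym = np.minimum(vals, vals.T)
    else:
        raise ValueError("symmetrize must be 'mean' or 'min'")
    genomes = list(m.index)
    g = nx.Graph()
    g.add_nodes_from(genomes)
    n = len(genomes)
    for i in range(n):
        for j in range(i + 1, n):
            if sym[i, j] >= threshold:
                g.add_edge(genomes[i], genomes[j])
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    labels = pd.Series(index=pd.Index(genomes, name="genome"), dtype=int)
    clusters: dict[int, tuple[str, ...]] = {}
    for cid, comp in enumerate(components, start=1):
        clusters[cid] = tuple(comp)
        labels.loc[comp] = cid

    idx = {gname: i for i, gname in enumerate(genomes)}
    within_rows = []
    for cid, comp in clusters.items():
        pair_vals = [
            sym[idx[a], idx[b]]
            for k, a in enumerate(comp)
            for b in comp[k + 1 :]
        ]
        within_rows.append(
            {
                "cluster": cid,
                "n_genomes": len(comp),
                "within_min": float(np.min(pair_vals)) if pair_vals else float("nan"),
                "within_median": float(np.median(pair_vals)) if pair_vals else float("nan"),
            }
        )
    within = pd.DataFrame(within_rows).set_index("cluster")
    between_vals = [
        sym[i, j]
        for i in range(n)
        for j in range(i + 1, n)
        if labels.iloc[i] != labels.iloc[j]
    ]
    return ClusterAssignment(
        labels=labels,
        threshold=float(threshold),
        within_stats=within,
        between_min=float(np.min(between_vals)) if between_vals else float("nan"),
        between_max=float(np.max(between_vals)) if between_vals else float("nan"),
        symmetrize=symmetrize,
        clusters=clusters,
    )


def genome_quality(completeness: float, contamination: float) -> float:
    """Dereplication quality score: completeness - 5 x contamination (%)."""
    if not 0 <= completeness <= 100:
        raise ValueError("completeness must be in [0, 100]")
    if contamination < 0:
        raise ValueError("contamination must be >= 0")
    return completeness - 5.0 * contamination


def env_abundance_correlation(
    sums: pd.DataFrame, env: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of per-subcluster abundance with an environment.

    ``sums`` is subcluster x sample (e.g. from :func:`subcluster_abundance`);
    ``env`` maps sample id to the environmental value. Samples missing
    either quantity are dropped pairwise per subcluster; fewer than 3
    complete pairs raises. Constant abundance yields a NaN correlation with
    ``defined=False``.
    """
    rows = []
    for subcluster, abundance in sums.iterrows():
        joined = pd.concat([abundance, env], axis=1, join="inner").dropna()
        n = len(joined)
        if n < 3:
            raise InsufficientSamplesError(
                f"subcluster {subcluster!r}: only {n} complete pairs (< 3)"
            )
        a = joined.iloc[:, 0].to_numpy()
        e = joined.iloc[:, 1].to_numpy()
        if np.ptp(a) == 0 or np.ptp(e) == 0:
            rho, defined = float("nan"), False
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = float(stats.spearmanr(a, e).statistic)
            defined = not np.isnan(rho)
        rows.append(
            {"subcluster": subcluster, "spearman_rho": rho, "n_samples": n, "defined": defined}
        )
    return pd.DataFrame(rows).set_index("subcluster")
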