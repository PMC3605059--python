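"""mRNA-per-polymerase "efficiency" and group-comparison statistics.

Efficiency is the ratio of steady-state mRNA signal (expression-array signal
summed over all probes of a gene) to the gene-body PRO-seq density — mRNA
produced per transcribing Pol II complex.  Group comparisons across cohesin
bins use the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .proseq_quant import pause_index


def aggregate_expression(probe_table: pd.DataFrame,
                         known_genes: set[str] | None = None) -> pd.Series:
    """Sum per-probe expression signals to per-gene totals.

    ``probe_table`` needs columns ``gene_id`` and ``signal``; genes with
    multiple probes are summed.  If ``known_genes`` is given, probes mapping
    to unknown gene ids raise an error listing the offenders.
    """
    if known_genes is not None:
        bad = sorted(set(probe_table["gene_id"]) - set(known_genes))
        if bad:
            raise ValueError(f"probes map to unknown gene ids: {bad}")
    out = probe_table.groupby("gene_id")["signal"].sum()
    return out.rename("mrna_signal")


def combine_body_density(quant: pd.DataFrame, gene_of_unit: pd.Series) -> pd.DataFrame:
    """Collapse multi-unit genes to one body density per gene.

    Density is recomputed as (sum of body RPM) / (sum of body lengths) over a
    gene's units, so long units weigh in proportionally.
    """
    df = quant[["body_rpm", "body_length"]].copy()
    df["gene_id"] = gene_of_unit.reindex(quant.index)
    g = df.groupby("gene_id")[["body_rpm", "body_length"]].sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        g["body_density"] = g["body_rpm"] / g["body_length"]
    g.loc[g["body_length"] == 0, "body_density"] = np.nan
    return g


def efficiency_table(mrna: dict[str, pd.Series] | pd.Series,
                     quant: dict[str, pd.DataFrame] | pd.DataFrame,
                     conditions: tuple[str, str] | None = None,
                     gene_of_unit: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene efficiency (mRNA / body density) per condition and its fold-change.

    ``mrna`` and ``quant`` map condition label -> per-gene mRNA signal /
    QuantTable (or are single objects for a one-condition table).  When
    ``conditions = (control, treated)`` the log2 efficiency fold-change
    between them is added.  ``gene_of_unit`` maps unit ids to gene ids for
    genes with several active transcription units; identity is assumed when
    omitted.  Genes with zero body density are flagged missing (NaN).
    """
    if isinstance(mrna, pd.Series):
        mrna = {"control": mrna}
    if isinstance(quant, pd.DataFrame):
        quant = {"control": quant}
    conds = list(quant)
    out: pd.DataFrame | None = None
    for cond in conds:
        q = quant[cond]
        if gene_of_unit is None:
            mapping = pd.Series(q.index, index=q.index)
        else:
            mapping = gene_of_unit
        dens = combine_body_density(q, mapping)
        m = mrna[cond] if cond in mrna else mrna[conds[0]]
        genes = dens.index.intersection(m.index)
        if len(genes) == 0:
            raise ValueError("no overlapping genes between expression and quant tables")
        df = pd.DataFrame({
            f"mrna_{cond}": m.reindex(genes),
            f"body_density_{cond}": dens["body_density"].reindex(genes),
        })
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = df[f"mrna_{cond}"] / df[f"body_density_{cond}"]
        df[f"efficiency_{cond}"] = eff.where(df[f"body_density_{cond}"] > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            df[f"log2_efficiency_{cond}"] = np.log2(df[f"efficiency_{cond}"])
        out = df if out is None else out.join(df, how="outer")
    if conditions is not None:
        c0, c1 = conditions
        with np.errstate(divide="ignore", invalid="ignore"):
            out["log2_efficiency_fc"] = (out[f"log2_efficiency_{c1}"]
                                         - out[f"log2_efficiency_{c0}"])
    out.index.name = "gene_id"
    return out


def group_distribution_test(values: pd.Series, groups: pd.Series,
                            comparisons: list[tuple[str, str]],
                            min_n: int = 2) -> pd.DataFrame:
    """Two-sample KS tests between cohesin groups.

    Missing values are dropped (and counted); groups below ``min_n``
    non-missing values yield a missing result with a warning.  P-values use
    the asymptotic KS distribution; no multiple-testing correction.
    """
    groups = groups.reindex(values.index)
    rows = []
    for g1, g2 in comparisons:
        x = values[groups == g1].dropna().to_numpy()
        y = values[groups == g2].dropna().to_numpy()
        n_missing = int(values[groups.isin([g1, g2])].isna().sum())
        if len(x) < min_n or len(y) < min_n:
            warnings.warn(f"group {g1} vs {g2}: below minimum size", stacklevel=2)
            rows.append({"group1": g1, "group2": g2, "D": np.nan, "p": np.nan,
                         "n1": len(x), "n2": len(y), "n_missing": n_missing})
            continue
        res = stats.ks_2samp(x, y, method="asymp")
        rows.append({"group1": g1, "group2": g2, "D": float(res.statistic),
                     "p": float(res.pvalue), "n1": len(x), "n2": len(y),
                     "n_missing": n_missing})
    return pd.DataFrame(rows)


def pause_index_by_group(quant: pd.DataFrame, groups: pd.Series,
                         active: pd.Series | None = None) -> pd.DataFrame:
    """Median pause index per cohesin group (active units only)."""
    pi = pause_index(quant)
    if active is not None:
        pi = pi[active.reindex(pi.index).fillna(False)]
    g = groups.reindex(pi.index)
    med = pi.groupby(g, observed=True).median()
    n = pi.groupby(g, observed=True).count()
    return pd.DataFrame({"median_pause_index": med, "n": n})
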