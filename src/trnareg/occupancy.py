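"""Pol III occupancy at tRNA genes: from per-feature ChIP counts (or
peak BED files) to housekeeping / repressed / inactive activity classes.

Pipeline: (1) exclude genes whose ChIP signal is confounded by
multimapping (>=25% multimapped reads and >=50 total reads, required in
every designated reference library); (2) call per-gene enrichment with a
per-feature Poisson test of IP against library-size-scaled input,
Benjamini-Hochberg corrected within each sample (significant at
adjusted p <= 0.05); (3) or, when a peak caller's BED output is supplied
instead, assign peak summits to tRNA genes within 125 bp; (4) intersect
replicate hit sets into per-cell-type consensus sets; (5) classify:
housekeeping = bound in all cell types, inactive = bound in none,
repressed = the union minus the housekeeping set.  Normalised signal
uses RLE (median-of-ratios) size factors times per-million library size,
reciprocally scaled.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gmean
from statsmodels.stats.multitest import multipletests

from .repertoire import rle_size_factors

__all__ = [
    "multimap_filter",
    "call_enrichment",
    "assign_peaks_to_trnas",
    "consensus_hits",
    "classify_activity",
    "normalized_signal",
    "nearest_trna_distance",
    "read_bed_intervals",
]

CLASSES = ("housekeeping", "repressed", "inactive")


def multimap_filter(
    multimap: pd.DataFrame,
    frac: float = 0.25,
    min_reads: int = 50,
    libraries: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split genes into (kept, excluded) by multimapping burden.

    ``multimap`` has columns ``gene``, ``library``, ``unique``,
    ``multi``.  A gene is excluded iff in *every* designated library
    (default: all libraries present) its multimapped fraction is
    >= ``frac`` AND its total reads are >= ``min_reads`` — the consensus
    of per-library exclusion calls.
    """
    df = multimap.copy()
    if libraries is not None:
        df = df[df["library"].isin(libraries)]
        if df.empty:
            raise ValueError("no rows for the designated libraries")
    total = df["unique"] + df["multi"]
    with np.errstate(invalid="ignore", divide="ignore"):
        mm_frac = np.where(total > 0, df["multi"] / total, 0.0)
    df = df.assign(_flag=(mm_frac >= frac) & (total >= min_reads))
    per_gene = df.groupby("gene")["_flag"].all()
    excluded = sorted(per_gene.index[per_gene])
    kept = sorted(per_gene.index[~per_gene])
    return kept, excluded


def _lam(input_col: pd.Series, scale: float, pseudo_lambda: float) -> np.ndarray:
    """Expected IP rate: scaled input, floored at the scaled mean input
    and at ``pseudo_lambda``."""
    x = input_col.to_numpy(dtype=float)
    return np.maximum.reduce([x * scale, np.full_like(x, x.mean() * scale),
                              np.full_like(x, pseudo_lambda)])


def call_enrichment(
    ip: pd.DataFrame,
    input_: pd.DataFrame,
    alpha: float = 0.05,
    pseudo_lambda: float = 1.0,
    scale_method: str = "library",
    background_quantile: float = 0.2,
) -> pd.DataFrame:
    """Per-feature Poisson enrichment of IP over matched input.

    For each sample, lambda_g is the scaled input count, floored at the
    scaled sample-wide mean input (the per-feature analogue of a peak
    caller's max-of-local-and-global background: using the raw noisy
    input count as a known Poisson rate is anticonservative whenever
    the input count happens to fall low) and at ``pseudo_lambda``.  The
    raw p-value is the upper-tail Poisson probability P(X >= ip_g),
    BH-adjusted across genes within the sample; significant iff
    adjusted p <= ``alpha``.  Returns a long DataFrame: gene, sample,
    ip, input, lam, enrichment, pvalue, padj, significant.

    ``scale_method="library"`` uses the ratio of total assigned reads
    IP/input.  That estimate is composition-biased when the count table
    covers only tRNA features and most of them are truly bound (the
    enriched reads inflate the IP total, deflating apparent
    enrichment); ``scale_method="background"`` instead estimates the
    depth ratio from unbound features: starting from the
    ``background_quantile`` quantile of per-gene IP/input ratios, genes
    called enriched are iteratively set aside and the scale re-estimated
    as the median ratio of the remainder, which debiases the estimate as
    long as a reasonable fraction of features is unbound.
    """
    if list(ip.columns) != list(input_.columns) or not ip.index.equals(input_.index):
        raise ValueError("IP and input tables must share genes and samples")
    if scale_method not in ("library", "background"):
        raise ValueError("scale_method must be 'library' or 'background'")
    recs = []
    for s in ip.columns:
        ip_tot, in_tot = float(ip[s].sum()), float(input_[s].sum())
        if ip_tot == 0 or in_tot == 0:
            raise ValueError(f"zero-depth library in sample {s!r}")
        k = ip[s].to_numpy()
        if scale_method == "library":
            scale = ip_tot / in_tot
        else:
            ratios = (ip[s] + 0.5) / (input_[s] + 0.5)
            scale = float(np.quantile(ratios, background_quantile))
            for _ in range(2):  # refine on apparent background genes
                lam = _lam(input_[s], scale, pseudo_lambda)
                padj = multipletests(stats.poisson.sf(k - 1, lam), method="fdr_bh")[1]
                bg = padj > alpha
                if bg.sum() >= 10:
                    scale = float(np.median(ratios[bg]))
        lam = _lam(input_[s], scale, pseudo_lambda)
        p = stats.poisson.sf(k - 1, lam)  # P(X >= k)
        padj = multipletests(p, method="fdr_bh")[1]
        recs.append(
            pd.DataFrame(
                {
                    "gene": ip.index,
                    "sample": s,
                    "ip": k,
                    "input": input_[s].to_numpy(),
                    "lam": lam,
                    "enrichment": k / lam,
                    "pvalue": p,
                    "padj": padj,
                    "significant": padj <= alpha,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED (>=3 columns; narrowPeak summit offset honoured when
    present as the 10th field)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rec = {
                "chrom": f[0],
                "start": int(f[1]),
                "end": int(f[2]),
                "name": f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
            }
            if len(f) >= 10:
                try:
                    off = int(f[9])
                    rec["summit"] = rec["start"] + off if off >= 0 else None
                except ValueError:
                    rec["summit"] = None
            rows.append(rec)
    return pd.DataFrame(rows)


def _point_to_interval_distance(p: int, start: int, end: int) -> int:
    """0 when the point falls inside [start, end); the base-gap otherwise."""
    if p < start:
        return start - p
    if p >= end:
        return p - (end - 1)
    return 0


def assign_peaks_to_trnas(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 125,
    *,
    multi_assign: bool = False,
) -> pd.DataFrame:
    """Assign peaks (by summit, else midpoint) to tRNA genes within
    ``window`` bp.

    ``peaks`` and ``genes`` are BED-style frames (0-based half-open)
    with ``chrom``/``start``/``end``/``name`` columns; peaks may carry a
    ``summit`` column.  By default each peak hits only its nearest gene
    (ties to the first by position); with ``multi_assign`` every gene
    within the window is reported.  Peaks on chromosomes absent from the
    gene set produce a warning and no assignment.
    """
    out = []
    gene_by_chrom = dict(tuple(genes.groupby("chrom")))
    missing = sorted(set(peaks["chrom"]) - set(gene_by_chrom))
    if missing:
        warnings.warn(
            f"peak chromosome(s) absent from gene annotation: {', '.join(missing)}",
            stacklevel=2,
        )
    for _, pk in peaks.iterrows():
        g = gene_by_chrom.get(pk["chrom"])
        if g is None:
            continue
        summit = pk.get("summit")
        if summit is None or (isinstance(summit, float) and np.isnan(summit)):
            summit = (int(pk["start"]) + int(pk["end"])) // 2
        summit = int(summit)
        d = np.array(
            [_point_to_interval_distance(summit, s, e) for s, e in zip(g["start"], g["end"])]
        )
        within = np.flatnonzero(d <= window)
        if len(within) == 0:
            continue
        if multi_assign:
            chosen = within
        else:
            chosen = [within[np.argmin(d[within])]]
        for i in chosen:
            out.append(
                {
                    "peak": pk["name"],
                    "gene": g["name"].iloc[i],
                    "distance": int(d[i]),
                }
            )
    return pd.DataFrame(out, columns=["peak", "gene", "distance"])


def consensus_hits(replicate_hits: list[set[str]]) -> set[str]:
    """Genes hit in every replicate of a condition (set intersection)."""
    if len(replicate_hits) < 2:
        raise ValueError("need >=2 replicates for a consensus")
    return set.intersection(*map(set, replicate_hits))


def classify_activity(
    consensus_by_celltype: dict[str, set[str]],
    filtered_genes: list[str],
) -> pd.DataFrame:
    """Partition filtered genes into housekeeping / repressed / inactive.

    housekeeping = genes in the consensus of every cell type; inactive =
    genes in no consensus; repressed = the union minus the housekeeping
    set.  Also records the per-cell-type consensus presence bits.
    """
    if len(consensus_by_celltype) < 2:
        raise ValueError("need >=2 cell types to classify activity")
    universe = set(filtered_genes)
    sets = {ct: s & universe for ct, s in consensus_by_celltype.items()}
    inter = set.intersection(*sets.values())
    union = set.union(*sets.values())
    rows = []
    for g in filtered_genes:
        if g in inter:
            cls = "housekeeping"
        elif g in union:
            cls = "repressed"
        else:
            cls = "inactive"
        row = {"gene": g, "class": cls}
        for ct, s in sets.items():
            row[f"bound_{ct}"] = g in s
        rows.append(row)
    return pd.DataFrame(rows)


def normalized_signal(counts: pd.DataFrame) -> pd.DataFrame:
    """RPM-scaled RLE-normalised signal.

    The median-of-ratios size factor absorbs both sequencing depth and
    composition; dividing it by library size leaves a pure composition
    factor (rescaled to geometric mean 1), and the signal is
    count * reciprocal(composition factor * library size / 1e6) —
    RPM scaling with an RLE composition correction, so uniformly
    doubling a library leaves the values unchanged.
    """
    factors = rle_size_factors(counts)
    libsize = counts.sum(axis=0)
    comp = factors / libsize
    comp = comp / gmean(comp)
    return counts / (comp * libsize / 1e6)


def nearest_trna_distance(genes: pd.DataFrame) -> pd.Series:
    """Distance from each gene to its nearest other tRNA gene.

    Gap between closest interval ends (0 for overlapping or book-ended
    intervals); genes alone on their chromosome get NaN.
    """
    if len(genes) < 2:
        raise ValueError("need >=2 genes")
    out = pd.Series(np.nan, index=genes["name"], dtype=float)
    for _, grp in genes.groupby("chrom"):
        if len(grp) < 2:
            continue
        g = grp.sort_values("start").reset_index(drop=True)
        n = len(g)
        starts, ends = g["start"].to_numpy(), g["end"].to_numpy()
        for i in range(n):
            best = np.inf
            for j in range(n):
                if i == j:
                    continue
                gap = max(starts[j] - ends[i], starts[i] - ends[j], 0)
                best = min(best, gap)
            out[g["name"].iloc[i]] = best
    return out
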