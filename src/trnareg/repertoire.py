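"""tRNA repertoire statistics from transcript-level count tables.

Counts are held as plain DataFrames: rows are features (transcripts or
anticodon families), columns are samples named ``<cell_type>_rep<k>``.
The analyses here turn counts into proportions of tRNA-mapped reads,
aggregate them over the isodecoder hierarchy, apply the detection
threshold (0.005% of tRNA-mapped reads by default), count major
isodecoders (the smallest set cumulatively holding >=90% of a family's
reads), and summarise anticodon-level buffering: fold changes of
individual transcripts across cell types are much larger than those of
whole anticodon pools when minor isodecoders swing and majors are
stable.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = [
    "sample_metadata",
    "proportions",
    "aggregate",
    "detection_filter",
    "major_isodecoder_count",
    "rle_size_factors",
    "buffering_summary",
]

_SAMPLE_RE = re.compile(r"^(?P<ct>.+)_rep(?P<rep>\d+)$")


def sample_metadata(columns) -> pd.DataFrame:
    """Parse ``<cell_type>_rep<k>`` sample names into metadata."""
    rows = []
    for c in columns:
        m = _SAMPLE_RE.match(str(c))
        if m is None:
            raise ValueError(f"sample name {c!r} not of the form <cell_type>_rep<k>")
        rows.append({"sample": c, "cell_type": m.group("ct"), "replicate": int(m.group("rep"))})
    return pd.DataFrame(rows).set_index("sample")


def _validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate feature ids in count table")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count table")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative entries in count table")


def proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Column-normalise counts to proportions of tRNA-mapped reads."""
    _validate_counts(counts)
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {', '.join(map(str, zero.index))}")
    return counts / totals


def aggregate(counts: pd.DataFrame, hierarchy: pd.DataFrame, level: str = "family") -> pd.DataFrame:
    """Sum counts over the hierarchy at ``level`` (``family``/``anticodon``/
    ``isotype``).  Integer totals are conserved exactly per sample."""
    _validate_counts(counts)
    key_col = "transcript" if "transcript" in hierarchy.columns else "gene"
    mapping = hierarchy.drop_duplicates(key_col).set_index(key_col)[level]
    missing = counts.index.difference(mapping.index)
    if len(missing):
        raise ValueError(f"features missing from hierarchy: {', '.join(map(str, missing[:5]))}")
    out = counts.groupby(mapping.reindex(counts.index)).sum()
    out.index.name = level
    return out


def detection_filter(
    props: pd.DataFrame,
    threshold: float = 5e-5,
    *,
    per_replicate: bool = False,
) -> tuple[pd.Index, pd.Index]:
    """Split features into detected / undetected sets.

    A feature is detected if its proportion reaches ``threshold``
    (default 0.005% of tRNA-mapped reads) in at least one cell type,
    using the mean over replicates per cell type (or each replicate
    separately when ``per_replicate``).
    """
    meta = sample_metadata(props.columns)
    if per_replicate:
        best = props.max(axis=1)
    else:
        by_ct = props.T.groupby(meta["cell_type"]).mean().T
        best = by_ct.max(axis=1)
    if threshold == 0:
        detected = props.index[(props > 0).any(axis=1)]
    else:
        detected = props.index[best >= threshold]
    return detected, props.index.difference(detected, sort=False)


def major_isodecoder_count(family_props, cutoff: float = 0.90) -> int:
    """Minimal number of isodecoders cumulatively holding >= ``cutoff``
    of an anticodon family's reads.

    Proportions are renormalised to sum to 1 within the family; the
    greedy prefix over descending proportions is optimal for this
    cumulative criterion.  Ties are broken by descending proportion then
    lexical feature id.
    """
    s = pd.Series(family_props, dtype=float)
    if len(s) == 0:
        raise ValueError("empty anticodon family")
    if s.sum() <= 0:
        raise ValueError("family has no reads")
    s = s / s.sum()
    s = s.sort_index().sort_values(ascending=False, kind="stable")
    cum = s.cumsum().to_numpy()
    return int(np.searchsorted(cum, cutoff - 1e-12) + 1)


def rle_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (RLE) size factors, rescaled to product 1.

    Factor_s = median over features (nonzero in all samples) of
    count_{f,s} / geometric-mean_f, then divided by the geometric mean
    of the factors so that their product is exactly 1.
    """
    _validate_counts(counts)
    full = counts[(counts > 0).all(axis=1)]
    if full.empty:
        raise ValueError("no feature with nonzero counts in every sample")
    gm = gmean(full, axis=1)
    ratios = full.div(gm, axis=0)
    factors = ratios.median(axis=0)
    factors = factors / gmean(factors)
    return factors


def _normalized_celltype_means(counts: pd.DataFrame) -> pd.DataFrame:
    factors = rle_size_factors(counts)
    norm = counts / factors
    meta = sample_metadata(counts.columns)
    return norm.T.groupby(meta["cell_type"]).mean().T


def buffering_summary(
    counts: pd.DataFrame,
    hierarchy: pd.DataFrame,
    reference: str,
    *,
    pseudocount: float = 0.5,
) -> dict:
    """Compare fold-change dispersion at transcript vs anticodon level.

    RLE-normalised counts are averaged over replicates per cell type;
    log2 fold changes (differentiated vs reference, with pseudocount)
    are computed per transcript and per anticodon family, and their
    dispersion (max |log2FC|, IQR) reported per level.  Buffering shows
    as strictly smaller dispersion at the anticodon level.
    """
    out: dict = {"reference": reference, "levels": {}}
    for level, table in (
        ("transcript", counts),
        ("anticodon", aggregate(counts, hierarchy, "family")),
    ):
        means = _normalized_celltype_means(table)
        if reference not in means.columns:
            raise ValueError(f"reference cell type {reference!r} not among samples")
        others = [c for c in means.columns if c != reference]
        lfc = np.log2(
            (means[others] + pseudocount).div(means[reference] + pseudocount, axis=0)
        )
        flat = lfc.to_numpy().ravel()
        out["levels"][level] = {
            "log2fc": lfc,
            "max_abs_log2fc": float(np.max(np.abs(flat))) if flat.size else float("nan"),
            "iqr_log2fc": float(np.subtract(*np.percentile(flat, [75, 25]))) if flat.size else float("nan"),
        }
    return out
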