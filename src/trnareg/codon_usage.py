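"""Transcriptome-weighted codon usage versus tRNA anticodon supply.

Codon demand is measured as proportional codon usage: the 61 sense-codon
frequencies of each coding transcript weighted by the transcript's TPM
in a sample, summed over transcripts, and normalised to proportions.
Start AUG codons are counted separately from coding-sequence AUGs, since
initiator and elongator Met are decoded by different tRNAs.

Codon supply is the proportional abundance of tRNA-mapped reads per
anticodon family, mapped onto all 61 sense codons: a codon gets its
Watson-Crick cognate anticodon's abundance when that family exists, and
otherwise the abundance of the wobble-capable donor family (G34 reads
codons ending C/U, U34 reads A/G, A34 acts as inosine reading U/C/A) is
duplicated onto it.  The wobble assignments ship as an editable TSV so
organism-specific decoding rules are data, not code.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Seq import Seq

from .simulate import SENSE_CODONS  # canonical 61 sense codons

__all__ = [
    "SENSE_CODONS",
    "transcript_codon_frequencies",
    "weighted_codon_usage",
    "default_wobble_table",
    "load_wobble_table",
    "map_supply_to_codons",
    "supply_demand_correlation",
    "codon_cv_across_samples",
]

_STOPS = ("TAA", "TAG", "TGA")

# wobble-capable base at anticodon position 34, by codon third base,
# in priority order (A34 is read as inosine after A-to-I editing)
_WOBBLE34 = {"T": ["G", "A"], "C": ["A"], "A": ["A"], "G": ["T"]}


def _codon_to_anticodon(codon: str) -> str:
    return str(Seq(codon).reverse_complement())


def transcript_codon_frequencies(cds: str) -> tuple[pd.Series, int]:
    """Count sense codons in a CDS, excluding the start AUG and the stop.

    Returns ``(counts over the 61 sense codons, start_AUG count)``.
    The CDS must begin with ATG, end with a stop codon, have length
    divisible by three and contain only A/C/G/T.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length is not a multiple of three")
    if set(cds) - set("ACGT"):
        raise ValueError("CDS contains ambiguous bases")
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not begin with an AUG codon")
    if cds[-3:] not in _STOPS:
        raise ValueError("CDS does not end with a stop codon")
    counts = pd.Series(0, index=pd.Index(SENSE_CODONS, name="codon"), dtype=int)
    for i in range(3, len(cds) - 3, 3):
        codon = cds[i : i + 3]
        if codon in _STOPS:
            raise ValueError(f"internal stop codon at position {i}")
        counts[codon] += 1
    return counts, 1


def weighted_codon_usage(
    cds: dict[str, str], tpm: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """TPM-weighted proportional codon usage per sample.

    ``usage[c, s] = sum_t freq(t, c) * TPM(t, s)`` normalised so the 61
    sense-codon proportions sum to 1 per sample.  Returns the usage
    table and the start-AUG usage (weighted start count divided by the
    same per-sample denominator).
    """
    expressed = tpm.index[(tpm > 0).any(axis=1)]
    missing = [t for t in expressed if t not in cds]
    if missing:
        raise ValueError(f"expressed transcripts without a CDS: {missing[:5]}")
    used = [t for t in tpm.index if t in cds]
    freq = pd.DataFrame(
        {t: transcript_codon_frequencies(cds[t])[0] for t in used}
    )  # 61 x transcripts
    w = tpm.loc[used]
    raw = freq.to_numpy() @ w.to_numpy()  # 61 x samples
    raw = pd.DataFrame(raw, index=freq.index, columns=tpm.columns)
    denom = raw.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0].tolist()
        raise ValueError(f"zero total codon usage in sample(s) {bad}")
    start_raw = w.sum(axis=0)  # one start AUG per transcript
    return raw / denom, start_raw / denom


def default_wobble_table() -> pd.DataFrame:
    """The shipped codon -> anticodon decoding table.

    Columns: ``codon``, ``wc_anticodon`` (Watson-Crick cognate) and
    ``wobble_donors`` (comma-separated anticodons in priority order used
    when the cognate family is absent).
    """
    rows = []
    for codon in SENSE_CODONS:
        wc = _codon_to_anticodon(codon)
        tail = wc[1:]
        donors = [b + tail for b in _WOBBLE34[codon[2]] if b + tail != wc]
        rows.append({"codon": codon, "wc_anticodon": wc, "wobble_donors": ",".join(donors)})
    return pd.DataFrame(rows)


def load_wobble_table(path: str | Path | None = None) -> pd.DataFrame:
    if path is None:
        with resources.as_file(
            resources.files("trnareg").joinpath("data/wobble_rules.tsv")
        ) as p:
            return pd.read_csv(p, sep="\t").fillna({"wobble_donors": ""})
    return pd.read_csv(path, sep="\t").fillna({"wobble_donors": ""})


def map_supply_to_codons(
    anticodon_props: pd.Series,
    wobble_table: pd.DataFrame | None = None,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Assign each of the 61 sense codons a cognate anticodon abundance.

    ``anticodon_props`` is indexed by anticodon (bare 3-mers or family
    names like ``Ala-AGC``).  Direct Watson-Crick assignment when the
    cognate family is present; otherwise the configured wobble donor's
    abundance is duplicated onto the codon.  Returns a DataFrame with
    columns ``supply``, ``anticodon``, ``provenance`` (direct /
    wobble-duplicated), indexed by codon.

    A complete tRNA repertoire covers all 61 codons; codons left with
    neither a cognate nor a wobble donor raise an error under
    ``strict`` (the default) and are silently dropped otherwise (useful
    for partial, e.g. subsampled, repertoires).
    """
    if wobble_table is None:
        wobble_table = load_wobble_table()
    idx = [str(i).split("-")[-1].upper() for i in anticodon_props.index]
    props = pd.Series(anticodon_props.to_numpy(dtype=float), index=idx)
    props = props.groupby(level=0).sum()

    rows = {}
    orphans = []
    for _, rec in wobble_table.iterrows():
        codon, wc = rec["codon"], rec["wc_anticodon"]
        donors = [d for d in str(rec["wobble_donors"]).split(",") if d]
        if wc in props.index:
            rows[codon] = {"supply": props[wc], "anticodon": wc, "provenance": "direct"}
            continue
        for d in donors:
            if d in props.index:
                rows[codon] = {
                    "supply": props[d],
                    "anticodon": d,
                    "provenance": "wobble-duplicated",
                }
                break
        else:
            orphans.append(codon)
    if orphans and strict:
        raise ValueError(
            "codon(s) with neither cognate nor wobble-donor anticodon present: "
            + ", ".join(orphans)
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "codon"
    covered = [c for c in wobble_table["codon"] if c in out.index]
    return out.loc[covered]


def supply_demand_correlation(usage: pd.Series, supply: pd.Series) -> dict:
    """Pearson correlation and least-squares fit of usage vs supply over
    the 61 codons."""
    common = usage.index.intersection(supply.index)
    if len(common) != len(usage) or len(common) != len(supply):
        raise ValueError("usage and supply must cover the same codons")
    x = supply.loc[common].to_numpy(dtype=float)
    y = usage.loc[common].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in usage or supply")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {"r": float(r), "p": float(p), "slope": float(fit.slope),
            "intercept": float(fit.intercept), "n": int(len(common))}


def codon_cv_across_samples(usage: pd.DataFrame) -> pd.Series:
    """Per-codon coefficient of variation (%) across cell types.

    Replicates are averaged per cell type first; CV = 100 * sd / mean
    over those per-type mean usages (sd with one delta degree of
    freedom).
    """
    from .repertoire import sample_metadata

    meta = sample_metadata(usage.columns)
    by_ct = usage.T.groupby(meta["cell_type"]).mean().T
    if by_ct.shape[1] < 2:
        raise ValueError("need >=2 cell types for a CV")
    mean = by_ct.mean(axis=1)
    if (mean == 0).any():
        raise ValueError("zero mean usage for some codon")
    sd = by_ct.std(axis=1, ddof=1)
    return 100.0 * sd / mean
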