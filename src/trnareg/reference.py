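"""tRNA gene references: GtRNAdb-style naming, curation, and the
gene / transcript / isodecoder / anticodon / isotype hierarchy.

A tRNA gene is named ``tRNA-<Isotype>-<Anticodon>-<isodecoder#>-<copy#>``
(e.g. ``tRNA-Pro-TGG-2-1``).  Genes sharing isotype, anticodon and
isodecoder number are identical gene copies encoding one transcript;
distinct transcripts sharing an anticodon are isodecoders of one
anticodon family; families charging the same amino acid form an isotype.

Mature-transcript curation follows standard tRNA biology: introns are
excised, tRNA-His receives the post-transcriptionally added 5' G-1, and
nuclear transcripts receive the 3' CCA tail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TRNAGene",
    "MatureTranscript",
    "GeneNameError",
    "parse_gene_name",
    "format_gene_name",
    "transcript_name",
    "curate_mature_reference",
    "aggregate_hierarchy",
    "read_gene_set",
    "write_gene_set",
    "write_mature_fasta",
]

_NAME_RE = re.compile(
    r"^(?P<mito>MT-)?tRNA-(?P<isotype>[A-Za-z]{3}|SeC|iMet)-"
    r"(?P<anticodon>[ACGTN]{3})-(?P<iso>\d+)-(?P<copy>\d+)$"
)


class GeneNameError(ValueError):
    """Raised when a gene name does not follow the GtRNAdb convention."""


def parse_gene_name(name: str) -> tuple[str, str, int, int]:
    """Parse ``tRNA-<Isotype>-<Anticodon>-<iso#>-<copy#>`` into its fields.

    Returns ``(isotype, anticodon, isodecoder_id, copy_id)``.  A leading
    ``MT-`` (mitochondrial) prefix is accepted and folded into the
    isotype as ``MT-<Isotype>``.

    >>> parse_gene_name("tRNA-Pro-TGG-2-1")
    ('Pro', 'TGG', 2, 1)
    """
    m = _NAME_RE.match(name)
    if m is None:
        # locate the offending token for a usable error message
        parts = name.split("-")
        if not name.startswith(("tRNA-", "MT-tRNA-")):
            raise GeneNameError(f"{name!r}: missing 'tRNA-' prefix")
        if len(parts) < 5:
            raise GeneNameError(f"{name!r}: expected 4 '-'-separated fields after 'tRNA'")
        core = parts[2] if parts[0] != "MT" else parts[3]
        raise GeneNameError(f"{name!r}: malformed token {core!r}")
    iso = m.group("isotype")
    if m.group("mito"):
        iso = "MT-" + iso
    return iso, m.group("anticodon").upper(), int(m.group("iso")), int(m.group("copy"))


def format_gene_name(isotype: str, anticodon: str, isodecoder_id: int, copy_id: int) -> str:
    """Inverse of :func:`parse_gene_name`."""
    if isotype.startswith("MT-"):
        return f"MT-tRNA-{isotype[3:]}-{anticodon}-{isodecoder_id}-{copy_id}"
    return f"tRNA-{isotype}-{anticodon}-{isodecoder_id}-{copy_id}"


def transcript_name(gene_name: str) -> str:
    """Gene name without the trailing copy number: all copies of one
    isodecoder encode the same transcript."""
    isotype, anticodon, iso, _copy = parse_gene_name(gene_name)
    prefix = "MT-tRNA" if isotype.startswith("MT-") else "tRNA"
    core = isotype[3:] if isotype.startswith("MT-") else isotype
    return f"{prefix}-{core}-{anticodon}-{iso}"


@dataclass
class TRNAGene:
    """One annotated tRNA locus (BED-style 0-based half-open coordinates)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    body_seq: str = ""
    flank5_seq: str = ""
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    bit_score: float | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.name}: end must exceed start")
        if self.strand not in "+-":
            raise ValueError(f"{self.name}: strand must be '+' or '-'")
        # validates the name eagerly
        self.isotype, self.anticodon, self.isodecoder_id, self.copy_id = parse_gene_name(
            self.name
        )

    @property
    def is_mito(self) -> bool:
        return self.isotype.startswith("MT-")

    @property
    def transcript(self) -> str:
        return transcript_name(self.name)

    @property
    def family(self) -> str:
        """Anticodon family key, e.g. ``Ala-AGC``."""
        return f"{self.isotype}-{self.anticodon}"


@dataclass
class MatureTranscript:
    transcript_name: str
    sequence: str


def _excise_introns(body: str, introns: Sequence[tuple[int, int]]) -> str:
    out = body
    for s, e in sorted(introns, reverse=True):
        if not (0 <= s < e <= len(body)):
            raise ValueError(f"intron [{s},{e}) out of bounds for body of length {len(body)}")
        out = out[:s] + out[e:]
    return out


def curate_mature_reference(
    genes: Iterable[TRNAGene],
    *,
    append_cca: bool = True,
    include_mito: bool = False,
) -> list[MatureTranscript]:
    """Build the mature tRNA sequence reference from gene bodies.

    Introns are excised, His transcripts get the 5' G, and nuclear
    transcripts get the 3' CCA (always appended by default; set
    ``append_cca=False`` if the template already carries it).  Copies of
    one isodecoder that yield identical mature sequences collapse to a
    single transcript.  Idempotent at the transcript level: curating the
    output sequences again leaves them unchanged only if ``append_cca``
    is disabled, so curation is defined on gene bodies, not transcripts.
    """
    seen: dict[str, str] = {}
    out: list[MatureTranscript] = []
    for g in genes:
        if g.is_mito and not include_mito:
            continue
        if not g.body_seq:
            raise ValueError(f"{g.name}: body sequence required for curation")
        seq = _excise_introns(g.body_seq.upper(), g.intron_intervals)
        if g.isotype == "His" and not g.is_mito:
            seq = "G" + seq
        if not g.is_mito and append_cca:
            seq = seq + "CCA"
        tname = g.transcript
        if tname in seen:
            if seen[tname] != seq:
                raise ValueError(
                    f"{tname}: copies produced differing mature sequences"
                )
            continue
        seen[tname] = seq
        out.append(MatureTranscript(tname, seq))
    return out


def aggregate_hierarchy(genes: Iterable[TRNAGene]) -> pd.DataFrame:
    """Tabulate the gene → transcript → anticodon family → isotype mapping.

    Returns a DataFrame with one row per gene and columns ``gene``,
    ``transcript``, ``isodecoder_id``, ``anticodon``, ``family``,
    ``isotype``.  Level counts come free via ``nunique``.
    """
    rows = [
        {
            "gene": g.name,
            "transcript": g.transcript,
            "isodecoder_id": g.isodecoder_id,
            "anticodon": g.anticodon,
            "family": g.family,
            "isotype": g.isotype,
        }
        for g in genes
    ]
    cols = ["gene", "transcript", "isodecoder_id", "anticodon", "family", "isotype"]
    df = pd.DataFrame(rows, columns=cols)
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene name {dup!r}")
    return df


def hierarchy_counts(hierarchy: pd.DataFrame) -> dict[str, int]:
    return {
        level: int(hierarchy[level].nunique())
        for level in ("gene", "transcript", "family", "isotype")
    }


# ---------------------------------------------------------------------------
# I/O

def read_gene_set(
    bed_path: str | Path,
    body_fasta: str | Path | None = None,
    flank_fasta: str | Path | None = None,
) -> list[TRNAGene]:
    """Read genes from BED6 plus optional body / 5'-flank FASTA keyed by name."""
    bodies = (
        {r.id: str(r.seq).upper() for r in SeqIO.parse(str(body_fasta), "fasta")}
        if body_fasta
        else {}
    )
    flanks = (
        {r.id: str(r.seq).upper() for r in SeqIO.parse(str(flank_fasta), "fasta")}
        if flank_fasta
        else {}
    )
    genes: list[TRNAGene] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"BED6 line with {len(f)} fields: {line!r}")
            chrom, start, end, name, score, strand = f[:6]
            score_val = None if score in (".", "") else float(score)
            genes.append(
                TRNAGene(
                    name=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    body_seq=bodies.get(name, ""),
                    flank5_seq=flanks.get(name, ""),
                    bit_score=score_val,
                )
            )
    return genes


def write_gene_set(genes: Sequence[TRNAGene], outdir: str | Path, prefix: str = "trna") -> dict[str, Path]:
    """Write BED6, gene-body FASTA and 5'-flank FASTA for a gene set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bed = outdir / f"{prefix}_genes.bed"
    with open(bed, "w") as fh:
        for g in genes:
            score = "0" if g.bit_score is None else f"{g.bit_score:g}"
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t{score}\t{g.strand}\n")
    body = outdir / f"{prefix}_bodies.fa"
    SeqIO.write(
        (SeqRecord(Seq(g.body_seq), id=g.name, description="") for g in genes),
        str(body),
        "fasta",
    )
    flank = outdir / f"{prefix}_flanks.fa"
    SeqIO.write(
        (SeqRecord(Seq(g.flank5_seq), id=g.name, description="") for g in genes),
        str(flank),
        "fasta",
    )
    return {"bed": bed, "body_fasta": body, "flank_fasta": flank}


def write_mature_fasta(transcripts: Sequence[MatureTranscript], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(t.sequence), id=t.transcript_name, description="") for t in transcripts),
        str(path),
        "fasta",
    )
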