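"""Seeded synthetic data with the statistical structure of a tRNA gene
regulation study: a multicopy tRNA gene set with planted promoter and
5'-flank motifs, negative-binomial transcript counts showing
minor-isodecoder repression in differentiated cell types, Pol III
ChIP IP/input counts following a planted activity-class design, and a
small coding transcriptome with TPM tables.

Design emulated: a pluripotent reference cell type plus differentiated
types, two replicates each.  Housekeeping genes are Pol III-bound in all
cell types and carry GC-rich and polyA elements in their 5' flanks;
inactive genes are never bound and carry polyT stretches (a Pol III
terminator signal); repressed genes are bound in the reference type only
and carry a weaker motif mixture.  Within each anticodon family one or
two "major" isodecoders stay highly expressed everywhere (modest 1.2-4x
shifts) while minor isodecoders are 10-70x repressed outside the
reference type, which buffers anticodon-level pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .reference import TRNAGene, format_gene_name, write_gene_set

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "CLASSES",
    "GC_MOTIF",
    "A_RUN",
    "T_RUN",
    "largest_remainder",
    "generate_gene_set",
    "generate_trna_counts",
    "generate_chip_counts",
    "generate_transcriptome",
    "simulate_all",
]

CLASSES = ("housekeeping", "repressed", "inactive")

# planted 5'-flank motifs (unambiguous at flank_length=200)
GC_MOTIF = "GCGGCGGCGC"
A_RUN = "AAAAAA"
T_RUN = "TTTTTTT"

# intragenic Pol III promoter consensus kernels planted in gene bodies
A_BOX = "TGGCGCAGTGG"
B_BOX = "GGTTCGAATCC"

_BASES = np.array(list("ACGT"))

_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    )
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``cell_types[0]`` is the pluripotent reference; all later types are
    "differentiated".  ``motif_effect`` in [0,1] scales how cleanly the
    class-specific flank motifs are planted (1 = every housekeeping
    flank carries the GC 10-mer and A6 run, every inactive flank the T7
    run; repressed flanks get a single motif at half that rate).
    ``nb_dispersion`` is phi in Var = mu + phi*mu^2.
    """

    n_genes: int = 90
    class_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_anticodon_families: int = 15
    duplicate_copy_rate: float = 0.1
    cell_types: tuple[str, ...] = ("iPSC", "CM", "NPC", "neuron")
    replicates_per_type: int = 2
    flank_length: int = 200
    motif_effect: float = 1.0
    nb_dispersion: float = 0.1
    mean_depth: float = 1_000_000.0
    seed: int = 0
    # transcriptome surface (coding genes, for codon-usage analyses)
    n_cds: int = 120
    cds_len_codons: tuple[int, int] = (60, 300)

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if not 0.0 <= self.duplicate_copy_rate <= 1.0:
            raise ValueError("duplicate_copy_rate must be in [0,1]")
        if self.n_anticodon_families > self.n_genes:
            raise ValueError("n_anticodon_families may not exceed n_genes")
        longest = max(len(GC_MOTIF) + len(A_RUN), len(T_RUN))
        if self.flank_length < longest:
            raise ValueError(f"flank_length must be >= {longest}")
        if not 0.0 <= self.motif_effect <= 1.0:
            raise ValueError("motif_effect must be in [0,1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if len(self.cell_types) < 2:
            raise ValueError("need a reference plus >=1 differentiated cell type")

    @property
    def reference(self) -> str:
        return self.cell_types[0]

    @property
    def samples(self) -> list[str]:
        return [
            f"{ct}_rep{r}"
            for ct in self.cell_types
            for r in range(1, self.replicates_per_type + 1)
        ]


@dataclass
class GroundTruth:
    """What the generator actually planted, for verification downstream."""

    genes: pd.DataFrame  # gene, transcript, class, family, isotype, anticodon, ...
    dup_groups: list[list[str]]
    motif_positions: dict[str, list[tuple[int, int, str]]]
    expression_means: pd.DataFrame | None = None  # transcript x cell type
    major_isodecoders: set[str] = field(default_factory=set)

    @property
    def labels(self) -> pd.Series:
        return self.genes.set_index("gene")["class"]

    def class_counts(self) -> dict[str, int]:
        vc = self.genes["class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}


def largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer parts by the largest-remainder method;
    ties broken by position order."""
    quotas = np.asarray(proportions, dtype=float) * n
    base = np.floor(quotas).astype(int)
    short = n - int(base.sum())
    remainders = quotas - base
    # stable sort descending on remainder -> earlier index wins ties
    order = np.argsort(-remainders, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, s: str, n_mut: int) -> str:
    if n_mut <= 0:
        return s
    s = list(s)
    pos = rng.choice(len(s), size=min(n_mut, len(s)), replace=False)
    for p in pos:
        alt = [b for b in "ACGT" if b != s[p]]
        s[p] = alt[rng.integers(0, 3)]
    return "".join(s)


def _plant(
    rng: np.random.Generator,
    flank: list[str],
    motif: str,
    occupied: list[tuple[int, int]],
    placed: list[tuple[int, int, str]],
    name: str,
) -> None:
    """Insert ``motif`` at a uniform-random position avoiding prior motifs."""
    L = len(flank)
    for _ in range(1000):
        start = int(rng.integers(0, L - len(motif) + 1))
        iv = (start, start + len(motif))
        if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
            flank[iv[0] : iv[1]] = list(motif)
            occupied.append(iv)
            placed.append((iv[0], iv[1], name))
            return
    raise RuntimeError("could not place motif without overlap")


# mutations per promoter box by activity class: promoter quality decays
# housekeeping -> repressed -> inactive
_BOX_MUTATIONS = {"housekeeping": 0, "repressed": 1, "inactive": 3}


def generate_gene_set(config: SimulationConfig) -> tuple[list[TRNAGene], GroundTruth]:
    """Generate a named multicopy tRNA gene set with planted class motifs.

    Gene bodies carry A-box/B-box kernels whose match quality decreases
    housekeeping -> repressed -> inactive; 5' flanks carry the planted
    class motifs with probability ``motif_effect`` (half rate and a
    single-motif mixture for repressed).  A ``duplicate_copy_rate``
    fraction of loci are exact extra copies (identical body and flank)
    of another gene of the same class, exercising multimapping logic.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    class_sizes = largest_remainder(n, config.class_proportions)

    n_dup = int(round(config.duplicate_copy_rate * n))
    # apportion duplicate loci across classes proportionally to class size
    total = max(sum(class_sizes), 1)
    dup_sizes = largest_remainder(n_dup, [c / total for c in class_sizes])
    dup_sizes = [min(d, max(c - 1, 0)) for d, c in zip(dup_sizes, class_sizes)]

    # anticodon families drawn from the sense-codon table
    codons = rng.choice(len(SENSE_CODONS), size=config.n_anticodon_families, replace=False)
    families = []
    for ci in codons:
        codon = SENSE_CODONS[ci]
        anticodon = str(Seq(codon).reverse_complement())
        isotype = seq3(str(Seq(codon).translate()))
        families.append((isotype, anticodon))

    genes: list[TRNAGene] = []
    rows = []
    motif_positions: dict[str, list[tuple[int, int, str]]] = {}
    dup_groups: list[list[str]] = []

    n_primary_total = n - sum(dup_sizes)
    # every family gets at least one primary transcript
    fam_of_primary = list(range(config.n_anticodon_families))
    extra = n_primary_total - config.n_anticodon_families
    if extra < 0:
        fam_of_primary = fam_of_primary[:n_primary_total]
        extra = 0
    fam_of_primary += list(rng.integers(0, config.n_anticodon_families, size=extra))
    rng.shuffle(fam_of_primary)

    iso_counter: dict[tuple[str, str], int] = {}
    coord = {"chr1": 10_000, "chr2": 10_000}
    chrom_names = list(coord)

    pi = 0  # primary cursor
    for cls, csize, dsize in zip(CLASSES, class_sizes, dup_sizes):
        n_prim = csize - dsize
        primaries: list[TRNAGene] = []
        for _ in range(n_prim):
            isotype, anticodon = families[fam_of_primary[pi]]
            pi += 1
            iso_counter[(isotype, anticodon)] = iso_counter.get((isotype, anticodon), 0) + 1
            iso_id = iso_counter[(isotype, anticodon)]
            name = format_gene_name(isotype, anticodon, iso_id, 1)

            body = list(_rand_seq(rng, 73))
            nmut = _BOX_MUTATIONS[cls]
            abox = _mutate(rng, A_BOX, nmut)
            bbox = _mutate(rng, B_BOX, nmut)
            body[7 : 7 + len(abox)] = list(abox)
            body[52 : 52 + len(bbox)] = list(bbox)
            body[33:36] = list(anticodon)
            body = "".join(body)

            flank = list(_rand_seq(rng, config.flank_length))
            occupied: list[tuple[int, int]] = []
            placed: list[tuple[int, int, str]] = []
            if cls == "housekeeping":
                if rng.random() < config.motif_effect:
                    _plant(rng, flank, GC_MOTIF, occupied, placed, "GC")
                    _plant(rng, flank, A_RUN, occupied, placed, "polyA")
            elif cls == "inactive":
                if rng.random() < config.motif_effect:
                    _plant(rng, flank, T_RUN, occupied, placed, "polyT")
            else:  # repressed: single motif from the mixture, at half rate
                if rng.random() < config.motif_effect / 2:
                    motif, mname = (GC_MOTIF, "GC") if rng.random() < 0.5 else (A_RUN, "polyA")
                    _plant(rng, flank, motif, occupied, placed, mname)
            flank = "".join(flank)

            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = coord[chrom]
            coord[chrom] = start + 73 + int(rng.integers(300, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = TRNAGene(name=name, chrom=chrom, start=start, end=start + 73,
                         strand=strand, body_seq=body, flank5_seq=flank)
            genes.append(g)
            primaries.append(g)
            motif_positions[name] = placed
            rows.append((name, cls))

        # duplicate loci: exact copies of a same-class primary
        hosts = rng.choice(len(primaries), size=dsize, replace=dsize > len(primaries))
        copy_counter: dict[str, int] = {}
        for hi in np.atleast_1d(hosts)[:dsize]:
            host = primaries[int(hi)]
            copy_counter[host.name] = copy_counter.get(host.name, 1) + 1
            name = format_gene_name(
                host.isotype, host.anticodon, host.isodecoder_id, copy_counter[host.name]
            )
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            start = coord[chrom]
            coord[chrom] = start + 73 + int(rng.integers(300, 5000))
            g = TRNAGene(name=name, chrom=chrom, start=start, end=start + 73,
                         strand=host.strand, body_seq=host.body_seq,
                         flank5_seq=host.flank5_seq)
            genes.append(g)
            motif_positions[name] = list(motif_positions[host.name])
            rows.append((name, cls))
            # record/extend the duplicate group of this host
            for grp in dup_groups:
                if host.name in grp:
                    grp.append(name)
                    break
            else:
                dup_groups.append([host.name, name])

    gene_df = pd.DataFrame(rows, columns=["gene", "class"])
    meta = pd.DataFrame(
        {
            "gene": [g.name for g in genes],
            "transcript": [g.transcript for g in genes],
            "family": [g.family for g in genes],
            "isotype": [g.isotype for g in genes],
            "anticodon": [g.anticodon for g in genes],
        }
    )
    gene_df = gene_df.merge(meta, on="gene")
    truth = GroundTruth(genes=gene_df, dup_groups=dup_groups, motif_positions=motif_positions)
    return genes, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with Var = mu + phi*mu^2 (Poisson at phi=0)."""
    mu = np.maximum(mu, 1e-12)
    if phi <= 0:
        return rng.poisson(mu)
    size = 1.0 / phi
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_trna_counts(
    genes: Sequence[TRNAGene],
    truth: GroundTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Transcript-level NB counts with major-isodecoder buffering.

    Within each anticodon family one or two major isodecoders keep high
    means in every cell type (differentiated:reference fold change in
    [1.2, 4]); minor isodecoders are expressed in the reference type and
    scaled down 10-70x in differentiated types.  Library totals are
    ~``mean_depth`` with lognormal(0, 0.1) per-sample jitter.  Fills
    ``truth.expression_means`` and ``truth.major_isodecoders``.
    """
    if not genes:
        raise ValueError("gene set is empty")
    rng = np.random.default_rng(config.seed + 1)
    df = truth.genes.drop_duplicates("transcript")
    transcripts = df["transcript"].tolist()
    fam = df.set_index("transcript")["family"]

    # skewed base abundances: major isodecoders dominate their family's
    # pool already in the reference type, as in real tRNA repertoires
    base = pd.Series(np.exp(rng.normal(np.log(50.0), 0.8, size=len(transcripts))),
                     index=transcripts)
    majors: set[str] = set()
    for f, members in fam.groupby(fam):
        ts = list(members.index)
        n_major = 1 if len(ts) == 1 else int(rng.integers(1, 3))
        picked = list(rng.choice(ts, size=n_major, replace=False))
        majors.update(picked)

    means = pd.DataFrame(index=transcripts, columns=list(config.cell_types), dtype=float)
    for t in transcripts:
        ref_mu = base[t] * (20.0 if t in majors else 1.0)
        means.loc[t, config.reference] = ref_mu
        for ct in config.cell_types[1:]:
            if t in majors:
                means.loc[t, ct] = ref_mu * rng.uniform(1.2, 4.0)
            else:
                means.loc[t, ct] = ref_mu / rng.uniform(10.0, 70.0)

    counts = {}
    for ct in config.cell_types:
        mu_ct = means[ct].to_numpy()
        for r in range(1, config.replicates_per_type + 1):
            depth = config.mean_depth * rng.lognormal(0.0, 0.1)
            scaled = mu_ct * depth / mu_ct.sum()
            counts[f"{ct}_rep{r}"] = _nb_draw(rng, scaled, config.nb_dispersion)
    out = pd.DataFrame(counts, index=transcripts)
    out.index.name = "transcript"
    truth.expression_means = means
    truth.major_isodecoders = majors
    return out


def generate_chip_counts(
    genes: Sequence[TRNAGene],
    truth: GroundTruth,
    config: SimulationConfig,
    *,
    background: float = 50.0,
    enrichment: float = 8.0,
    multimap_rate_dup: float = 0.6,
    multimap_rate_solo: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene IP and input Poisson counts plus a multimapping table.

    Input counts are Poisson(background); IP counts are
    Poisson(background * enrichment) where the planted design says the
    gene is Pol III-bound in that cell type (housekeeping: all types;
    repressed: reference only; inactive: never).  Members of a
    duplicate-copy group share a multimapped read pool split equally;
    the multimap table covers the reference cell type's IP libraries.
    """
    if not genes:
        raise ValueError("gene set is empty")
    rng = np.random.default_rng(config.seed + 2)
    names = [g.name for g in genes]
    labels = truth.labels

    def active(gene: str, ct: str) -> bool:
        cls = labels[gene]
        if cls == "housekeeping":
            return True
        if cls == "repressed":
            return ct == config.reference
        return False

    ip = {}
    inp = {}
    for ct in config.cell_types:
        for r in range(1, config.replicates_per_type + 1):
            s = f"{ct}_rep{r}"
            j_ip = rng.lognormal(0.0, 0.1)
            j_in = rng.lognormal(0.0, 0.1)
            enr = np.array([enrichment if active(g, ct) else 1.0 for g in names])
            ip[s] = rng.poisson(background * j_ip * enr)
            inp[s] = rng.poisson(np.full(len(names), background * j_in))
    ip_df = pd.DataFrame(ip, index=names)
    inp_df = pd.DataFrame(inp, index=names)
    ip_df.index.name = inp_df.index.name = "gene"

    in_dup = {g for grp in truth.dup_groups for g in grp}
    ref_libs = [f"{config.reference}_rep{r}" for r in range(1, config.replicates_per_type + 1)]
    mm_rows = []
    for lib in ref_libs:
        unique = ip_df[lib]
        multi = pd.Series(0, index=names)
        for grp in truth.dup_groups:
            grp_total = int(unique.loc[grp].sum())
            pool = rng.poisson(multimap_rate_dup / (1 - multimap_rate_dup) * max(grp_total, 1))
            share = pool // len(grp)
            for g in grp:
                multi.loc[g] = share
        solo = [g for g in names if g not in in_dup]
        multi.loc[solo] = rng.poisson(
            multimap_rate_solo / (1 - multimap_rate_solo) * np.maximum(unique.loc[solo], 1)
        )
        for g in names:
            mm_rows.append((g, lib, int(unique[g]), int(multi[g])))
    mm = pd.DataFrame(mm_rows, columns=["gene", "library", "unique", "multi"])
    return ip_df, inp_df, mm


def generate_transcriptome(config: SimulationConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Small coding transcriptome: structurally valid CDS plus TPM tables.

    Every CDS begins with ATG, ends with a stop, has length divisible by
    three and no ambiguous bases.  TPM columns sum to 1e6 per sample.
    """
    rng = np.random.default_rng(config.seed + 3)
    bias = rng.dirichlet(np.full(len(SENSE_CODONS), 5.0))
    cds: dict[str, str] = {}
    lo, hi = config.cds_len_codons
    for i in range(config.n_cds):
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(SENSE_CODONS), size=n_codons - 1, p=bias)
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        cds[f"TX{i + 1:04d}"] = "ATG" + "".join(SENSE_CODONS[j] for j in body) + stop

    tpm = {}
    for ct in config.cell_types:
        alpha = rng.uniform(0.5, 2.0, size=config.n_cds)
        for r in range(1, config.replicates_per_type + 1):
            w = rng.dirichlet(alpha * 20)
            tpm[f"{ct}_rep{r}"] = w * 1e6
    tpm_df = pd.DataFrame(tpm, index=list(cds))
    tpm_df.index.name = "transcript"
    return cds, tpm_df


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator and write the standard text outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, truth = generate_gene_set(config)
    paths = write_gene_set(genes, outdir)

    counts = generate_trna_counts(genes, truth, config)
    paths["trna_counts"] = outdir / "trna_counts.tsv"
    counts.to_csv(paths["trna_counts"], sep="\t")

    ip, inp, mm = generate_chip_counts(genes, truth, config)
    paths["chip_ip"] = outdir / "chip_ip_counts.tsv"
    paths["chip_input"] = outdir / "chip_input_counts.tsv"
    paths["multimap"] = outdir / "chip_multimap.tsv"
    ip.to_csv(paths["chip_ip"], sep="\t")
    inp.to_csv(paths["chip_input"], sep="\t")
    mm.to_csv(paths["multimap"], sep="\t", index=False)

    cds, tpm = generate_transcriptome(config)
    paths["cds_fasta"] = outdir / "cds.fa"
    with open(paths["cds_fasta"], "w") as fh:
        for name, seq in cds.items():
            fh.write(f">{name}\n{seq}\n")
    paths["tpm"] = outdir / "tpm.tsv"
    tpm.to_csv(paths["tpm"], sep="\t")

    paths["ground_truth"] = outdir / "ground_truth.tsv"
    truth.genes.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
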