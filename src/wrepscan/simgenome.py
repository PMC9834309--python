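"""Synthetic WZ/ZZ genomes with planted repeat families and read simulation.

Builds female (autosomes + Z + W) and male (autosomes + Z) haploid sequence
sets in which repeat families are planted at known per-compartment copy
numbers, then simulates low-coverage single-end reads per individual. Every
planted copy is recorded in a :class:`TruthManifest`, so downstream stages
(clustering, enrichment testing, coverage mapping) can be validated against
ground truth.

The karyotype model is female-heterogametic (WZ females, ZZ males), the
standard lepidopteran arrangement. Autosome and Z sequences are shared
between the sexes; the W is female-limited. Reads are drawn uniformly from
the *diploid* complement (two autosome sets plus ZW or ZZ), which means a
W-limited repeat is covered at roughly half the per-copy depth of a diploid
autosomal locus. This dosage effect is intentional and mirrors real
sequencing: coverage-based copy-number estimates for W repeats are
haploid-genome equivalents, about half the per-cell W copy count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.FastaIO import FastaWriter

from .seqs import mutate, random_dna, revcomp

SEX_FEMALE = "F"
SEX_MALE = "M"

#: ploidy of each compartment in one individual, by sex
PLOIDY = {
    SEX_FEMALE: {"A": 2, "Z": 1, "W": 1},
    SEX_MALE: {"A": 2, "Z": 2},
}

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Deletion:
    """An internal deletion carried by a fraction of W-compartment copies.

    ``start_0based``/``length_bp`` locate the deleted interval inside the
    family monomer (0-based, half-open). ``carrier_fraction`` is the
    fraction of W copies planted as deletion carriers; the realized carrier
    count is rounded to the nearest integer, ties up.
    """

    start_0based: int
    length_bp: int
    carrier_fraction: float

    def __post_init__(self) -> None:
        if self.start_0based < 0 or self.length_bp <= 0:
            raise ValueError("deletion interval must have start >= 0 and length > 0")
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError(
                f"carrier_fraction must be in [0, 1], got {self.carrier_fraction}"
            )

    @property
    def end_0based(self) -> int:
        return self.start_0based + self.length_bp


@dataclass(frozen=True)
class RepeatFamily:
    """A repeat family to plant: monomer plus per-compartment copy numbers.

    ``divergence`` is the per-copy substitution rate applied independently
    to every planted copy, emulating the sequence heterogeneity of a real
    repeat family.
    """

    name: str
    monomer: str
    copies_w: int = 0
    copies_z: int = 0
    copies_autosome: int = 0
    divergence: float = 0.05
    deletion: Optional[Deletion] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("family name must be non-empty")
        if not self.monomer or not set(self.monomer) <= _VALID_BASES:
            raise ValueError(
                f"monomer of family {self.name!r} must be non-empty A/C/G/T"
            )
        for attr in ("copies_w", "copies_z", "copies_autosome"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} of family {self.name!r} must be >= 0")
        if not 0.0 <= self.divergence < 0.3:
            raise ValueError(
                f"divergence of family {self.name!r} must be in [0, 0.3)"
            )
        if self.deletion is not None and self.deletion.end_0based > len(self.monomer):
            raise ValueError(
                f"deletion interval of family {self.name!r} extends past the monomer "
                f"({self.deletion.end_0based} > {len(self.monomer)})"
            )

    @property
    def monomer_length(self) -> int:
        return len(self.monomer)

    def deleted_monomer(self) -> str:
        """Monomer with the internal deletion applied."""
        if self.deletion is None:
            raise ValueError(f"family {self.name!r} has no deletion variant")
        d = self.deletion
        return self.monomer[: d.start_0based] + self.monomer[d.end_0based :]

    def carrier_count(self) -> int:
        """Number of W copies planted as deletion carriers.

        Nearest integer, ties rounded up (e.g. 17% of 353 copies -> 60).
        """
        if self.deletion is None:
            return 0
        return int(math.floor(self.deletion.carrier_fraction * self.copies_w + 0.5))


@dataclass(frozen=True)
class GenomeSpec:
    """Sizing and background-composition parameters for one genome build.

    ``genome_size_bp`` is the haploid female genome (autosomes + Z + W);
    the default matches a lepidopteran-scale genome of 631 Mb and is meant
    to be scaled down for desk-size runs. ``w_fraction``/``z_fraction``
    apportion the haploid genome to the sex chromosomes; the background is
    i.i.d. nucleotides at the requested GC (default 0.38, a typical
    lepidopteran value).
    """

    genome_size_bp: int = 631_000_000
    w_fraction: float = 0.15
    z_fraction: float = 0.15
    gc: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise ValueError("genome_size_bp must be positive")
        for attr in ("w_fraction", "z_fraction", "gc"):
            v = getattr(self, attr)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{attr} must be in (0, 1), got {v}")
        if self.w_fraction + self.z_fraction >= 1.0:
            raise ValueError("w_fraction + z_fraction must be < 1")

    def compartment_sizes(self) -> dict[str, int]:
        w = int(round(self.genome_size_bp * self.w_fraction))
        z = int(round(self.genome_size_bp * self.z_fraction))
        return {"A": self.genome_size_bp - w - z, "Z": z, "W": w}


@dataclass(frozen=True)
class Insert:
    """One planted repeat copy: where it landed and what was realized."""

    family: str
    compartment: str
    start: int  # 0-based, half-open on the named compartment sequence
    end: int
    carrier: bool
    n_substitutions: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthManifest:
    """Ground truth for a synthetic genome build.

    Records every planted insert (0-based, half-open coordinates) plus the
    compartment sizes; the key for parameter-recovery tests.
    """

    inserts: list[Insert] = field(default_factory=list)
    compartment_sizes: dict[str, int] = field(default_factory=dict)

    def count(self, family: str, compartment: str | None = None) -> int:
        return sum(
            1
            for ins in self.inserts
            if ins.family == family
            and (compartment is None or ins.compartment == compartment)
        )

    def carriers(self, family: str) -> int:
        return sum(1 for ins in self.inserts if ins.family == family and ins.carrier)

    def intervals(self, family: str, compartment: str) -> list[tuple[int, int]]:
        return [
            (ins.start, ins.end)
            for ins in self.inserts
            if ins.family == family and ins.compartment == compartment
        ]

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for ins in self.inserts:
            seen.setdefault(ins.family, None)
        return list(seen)

    def family_of(self, compartment: str, start: int, end: int) -> Optional[str]:
        """Family whose insert covers the majority of [start, end), if any."""
        best_name, best_ov = None, 0
        for ins in self.inserts:
            if ins.compartment != compartment:
                continue
            ov = min(end, ins.end) - max(start, ins.start)
            if ov > best_ov:
                best_name, best_ov = ins.family, ov
        if best_ov * 2 > (end - start):
            return best_name
        return None

    def expected_copy_equivalent(self, family: str, sex: str) -> float:
        """Haploid-equivalent copy number a coverage estimator should see.

        Copy-number estimates divide element depth by genome fold-coverage
        (read bases / haploid genome size). Reads are drawn uniformly from
        the diploid complement, so per-copy depth is read_bases / diploid
        size while genome coverage is read_bases / haploid size; the
        estimator therefore sees

            (sum over compartments of copies x ploidy) x haploid / diploid.

        For a genome whose sex chromosomes are a small fraction of the
        total this reduces to the familiar dosage rule — autosomal copies
        count fully, single-copy-compartment (W, female Z) copies count
        half — but the exact ratio is used here because scaled-down test
        genomes give the W a non-negligible share.
        """
        ploidy = PLOIDY[sex]
        haploid = sum(self.compartment_sizes[c] for c in ploidy)
        diploid = sum(self.compartment_sizes[c] * p for c, p in ploidy.items())
        copies_diploid = sum(
            self.count(family, comp) * p for comp, p in ploidy.items()
        )
        return copies_diploid * haploid / diploid

    # ------------------------------------------------------------------ I/O

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# wrepscan truth manifest\n")
            fh.write("# coordinates: 0-based, half-open, on compartment sequences\n")
            for name, size in sorted(self.compartment_sizes.items()):
                fh.write(f"# compartment\t{name}\t{size}\n")
            fh.write("family\tcompartment\tstart\tend\tcarrier\tn_substitutions\n")
            for ins in self.inserts:
                fh.write(
                    f"{ins.family}\t{ins.compartment}\t{ins.start}\t{ins.end}\t"
                    f"{int(ins.carrier)}\t{ins.n_substitutions}\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "TruthManifest":
        sizes: dict[str, int] = {}
        inserts: list[Insert] = []
        header_seen = False
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    parts = line[1:].strip().split("\t")
                    if parts and parts[0] == "compartment":
                        sizes[parts[1]] = int(parts[2])
                    continue
                if not line:
                    continue
                if not header_seen:
                    header_seen = True  # column header
                    continue
                fam, comp, start, end, carrier, nsub = line.split("\t")
                inserts.append(
                    Insert(fam, comp, int(start), int(end), bool(int(carrier)), int(nsub))
                )
        return cls(inserts=inserts, compartment_sizes=sizes)


@dataclass
class ReadSet:
    """One individual's reads with its sex label.

    ``reads`` holds (id, sequence, quality-or-None) triples; qualities are
    phred+33 strings when present.
    """

    individual_id: str
    sex: str
    reads: list[tuple[str, str, Optional[str]]]
    read_length_bp: int

    def __post_init__(self) -> None:
        if self.sex not in (SEX_FEMALE, SEX_MALE):
            raise ValueError(f"sex must be {SEX_FEMALE!r} or {SEX_MALE!r}")

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# genome construction


def expected_read_count(depth: float, genome_size_bp: int, read_length_bp: int) -> int:
    """Number of reads for a target fold-coverage: round(depth * G / L)."""
    return int(round(depth * genome_size_bp / read_length_bp))


def _plant_compartment(
    rng: np.random.Generator,
    name: str,
    size: int,
    copies: list[tuple[RepeatFamily, bool]],
    gc: float,
) -> tuple[str, list[Insert]]:
    """Build one compartment: i.i.d. background with copies at random gaps."""
    total_planted = sum(
        len(fam.deleted_monomer()) if carrier else fam.monomer_length
        for fam, carrier in copies
    )
    if total_planted > size:
        raise ValueError(
            f"planted repeat bases ({total_planted}) exceed the size of "
            f"compartment {name!r} ({size})"
        )
    if not copies:
        return random_dna(rng, size, gc), []

    order = rng.permutation(len(copies))
    free = size - total_planted
    n = len(copies)
    gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))

    pieces: list[str] = []
    inserts: list[Insert] = []
    pos = 0
    for slot, oi in enumerate(order):
        gap = int(gaps[slot])
        if gap:
            pieces.append(random_dna(rng, gap, gc))
            pos += gap
        fam, carrier = copies[int(oi)]
        template = fam.deleted_monomer() if carrier else fam.monomer
        seq, nsub = mutate(rng, template, fam.divergence)
        pieces.append(seq)
        inserts.append(Insert(fam.name, name, pos, pos + len(seq), carrier, nsub))
        pos += len(seq)
    tail = int(gaps[n])
    if tail:
        pieces.append(random_dna(rng, tail, gc))
    return "".join(pieces), inserts


def build_genomes(
    spec: GenomeSpec, families: Iterable[RepeatFamily]
) -> tuple[dict[str, str], dict[str, str], TruthManifest]:
    """Construct female and male haploid sequence sets plus the truth manifest.

    Autosome and Z sequences are shared between the sexes (identical
    objects); the W appears only in the female set. Copy placement is
    non-overlapping with i.i.d. background in the gaps. Identical
    (spec, families) inputs and seed reproduce identical output.
    """
    families = list(families)
    rng = np.random.default_rng(spec.seed)
    sizes = spec.compartment_sizes()

    per_comp: dict[str, list[tuple[RepeatFamily, bool]]] = {"A": [], "Z": [], "W": []}
    for fam in families:
        per_comp["A"].extend((fam, False) for _ in range(fam.copies_autosome))
        per_comp["Z"].extend((fam, False) for _ in range(fam.copies_z))
        n_carrier = fam.carrier_count()
        for i in range(fam.copies_w):
            per_comp["W"].append((fam, i < n_carrier))

    seqs: dict[str, str] = {}
    manifest = TruthManifest(compartment_sizes=dict(sizes))
    for comp in ("A", "Z", "W"):
        seq, inserts = _plant_compartment(rng, comp, sizes[comp], per_comp[comp], spec.gc)
        seqs[comp] = seq
        manifest.inserts.extend(inserts)

    female = {"A": seqs["A"], "Z": seqs["Z"], "W": seqs["W"]}
    male = {"A": seqs["A"], "Z": seqs["Z"]}
    return female, male, manifest


# ---------------------------------------------------------------------------
# read simulation

_Q30_CHAR = chr(30 + 33)


def read_origin(read_id: str) -> tuple[str, int, str]:
    """Parse a simulated read id into (compartment, 0-based start, strand).

    Any tag prefixes added downstream are tolerated: the provenance fields
    are the last three '|'-separated components.
    """
    parts = read_id.split("|")
    if len(parts) < 4:
        raise ValueError(f"read id {read_id!r} carries no simulator provenance")
    comp, start, strand = parts[-3], parts[-2], parts[-1]
    return comp, int(start), strand


def simulate_reads(
    genomes: dict[str, str],
    sex: str,
    depth: float,
    read_length_bp: int,
    error_rate: float = 0.0,
    seed: int = 0,
    individual_id: str = "ind",
) -> ReadSet:
    """Simulate uniform single-end reads from one individual's diploid genome.

    The read count is round(depth * haploid_size / read_length) where the
    haploid size is the sum of this sex's compartments. Reads are drawn
    uniformly over valid start positions of the diploid complement (two
    autosome sets, ZW or ZZ), reverse-complemented with probability 0.5,
    and subjected to i.i.d. substitution errors at ``error_rate``. Read ids
    encode provenance as ``<individual>:<i>|<compartment>|<start>|<strand>``.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    if read_length_bp <= 0:
        raise ValueError(f"read_length_bp must be positive, got {read_length_bp}")
    shortest = min(len(s) for s in genomes.values())
    if read_length_bp > shortest:
        raise ValueError(
            f"read length {read_length_bp} exceeds the shortest compartment ({shortest})"
        )
    ploidy = PLOIDY[sex] if sex in PLOIDY else None
    if ploidy is None:
        raise ValueError(f"unknown sex {sex!r}")

    haploid_size = sum(len(s) for s in genomes.values())
    n_reads = expected_read_count(depth, haploid_size, read_length_bp)

    # one entry per haplotype copy of each compartment
    sources: list[tuple[str, str]] = []
    for comp, seq in genomes.items():
        for _ in range(ploidy.get(comp, 0)):
            sources.append((comp, seq))
    valid = np.array([len(seq) - read_length_bp + 1 for _, seq in sources])
    cum = np.cumsum(valid)

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, cum[-1], size=n_reads)
    strands = rng.random(n_reads) < 0.5
    qual = _Q30_CHAR * read_length_bp

    reads: list[tuple[str, str, Optional[str]]] = []
    for i in range(n_reads):
        src = int(np.searchsorted(cum, draws[i], side="right"))
        start = int(draws[i] - (cum[src - 1] if src else 0))
        comp, seq = sources[src]
        frag = seq[start : start + read_length_bp]
        strand = "-" if strands[i] else "+"
        if strand == "-":
            frag = revcomp(frag)
        if error_rate > 0:
            frag, _ = mutate(rng, frag, error_rate)
        rid = f"{individual_id}:{i:06d}|{comp}|{start}|{strand}"
        reads.append((rid, frag, qual))
    return ReadSet(individual_id, sex, reads, read_length_bp)


# ---------------------------------------------------------------------------
# fixture I/O


def _write_fasta(path: Path, records: Iterable[tuple[str, str]]) -> None:
    with path.open("w") as fh:
        writer = FastaWriter(fh, wrap=80)
        writer.write_file(
            SeqRecord(Seq(seq), id=name, description="") for name, seq in records
        )


def write_fixture(
    out_dir: str | Path,
    female: dict[str, str],
    male: dict[str, str],
    readsets: Iterable[ReadSet],
    manifest: TruthManifest,
) -> dict[str, Path]:
    """Write a complete synthetic fixture: FASTA genomes, FASTQ reads, manifest.

    Returns the paths written, keyed by artifact name. Re-reading with
    :func:`read_fixture` reproduces the objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome_female"] = out / "genome_female.fasta"
    _write_fasta(paths["genome_female"], sorted(female.items()))
    paths["genome_male"] = out / "genome_male.fasta"
    _write_fasta(paths["genome_male"], sorted(male.items()))

    for rs in readsets:
        p = out / f"reads_{rs.individual_id}.fastq"
        with p.open("w") as fh:
            for rid, seq, qual in rs.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")
        paths[f"reads_{rs.individual_id}"] = p

    paths["manifest"] = out / "manifest.tsv"
    manifest.write(paths["manifest"])
    return paths


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path: str | Path) -> list[tuple[str, str, Optional[str]]]:
    """Read FASTA or FASTQ reads (format chosen by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    out: list[tuple[str, str, Optional[str]]] = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def read_fixture(out_dir: str | Path) -> tuple[dict[str, str], dict[str, str], TruthManifest]:
    out = Path(out_dir)
    female = read_fasta(out / "genome_female.fasta")
    male = read_fasta(out / "genome_male.fasta")
    manifest = TruthManifest.read(out / "manifest.tsv")
    return female, male, manifest


def random_monomer(length: int, gc: float = 0.38, seed: int = 0) -> str:
    """Convenience: a reproducible random monomer for configured families."""
    return random_dna(np.random.default_rng(seed), length, gc)
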