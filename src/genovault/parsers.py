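"""Text-format parsers: manifest.ini, FASTA, GTF, VCF, FASTQ, CSV.

These are deliberately small, strict parsers for the dialects the store
ingests.  Coordinates are converted to the internal 0-based half-open
convention here, at the boundary, and converted back on export —
downstream code never sees 1-based coordinates.

VCF records are normalized at parse time: the shared leading base of
REF/ALT (the VCF anchor) is trimmed so that every polymorphism is exactly
one of substitution (1 base -> 1 base), insertion (0 -> k bases, anchored
after a position) or deletion (k -> 0 bases).  Normalization is
idempotent.
"""

from __future__ import annotations

import configparser
import csv as _csv
import io
from dataclasses import dataclass, field

from .errors import (
    AlphabetError,
    CoordinateError,
    FormatError,
    ManifestError,
)
from .sequence import NUCLEOTIDE_ALPHABET

# ---------------------------------------------------------------------------
# manifest.ini

MANIFEST_ROLES = ("fasta", "gtf", "snp")


@dataclass
class DatawrapManifest:
    """Metadata of one datawrap (archive or directory of data files).

    ``files`` maps a role (fasta/gtf/snp) to archive-member paths or URLs;
    URL entries are recorded and flagged, never fetched.
    """

    description: str
    version: str
    maintainer: str
    species: str
    kind: str                       # "genome" | "snps"
    name: str
    files: list[tuple[str, str]] = field(default_factory=list)

    @property
    def remote_files(self) -> list[tuple[str, str]]:
        return [(r, p) for (r, p) in self.files if is_remote(p)]

    def paths(self, role: str) -> list[str]:
        return [p for (r, p) in self.files if r == role]

    def as_dict(self) -> dict:
        return {
            "description": self.description,
            "version": self.version,
            "maintainer": self.maintainer,
            "species": self.species,
            "kind": self.kind,
            "name": self.name,
            "files": list(self.files),
        }


def is_remote(location: str) -> bool:
    return location.startswith(("http://", "https://", "ftp://"))


def parse_manifest(text: str) -> DatawrapManifest:
    """Parse a manifest.ini.

    Layout: ``[package]`` description/version/maintainer, one of
    ``[genome]`` or ``[snps]`` with name/species, and ``[files]`` whose
    keys start with a role (``fasta``, ``gtf``, ``snp``; a numeric suffix
    such as ``fasta2`` allows several files per role).
    """
    cp = configparser.ConfigParser()
    try:
        cp.read_string(text)
    except configparser.Error as e:
        raise ManifestError(f"unparseable manifest.ini: {e}") from e

    if "package" not in cp:
        raise ManifestError("manifest missing [package] section")
    pkg = cp["package"]
    for key in ("description", "version", "maintainer"):
        if key not in pkg:
            raise ManifestError(f"manifest missing mandatory key {key!r}")

    if "genome" in cp and "snps" in cp:
        raise ManifestError("manifest declares both [genome] and [snps]")
    if "genome" in cp:
        kind, section = "genome", cp["genome"]
    elif "snps" in cp:
        kind, section = "snps", cp["snps"]
    else:
        raise ManifestError("manifest missing [genome] or [snps] section")
    for key in ("name", "species"):
        if key not in section:
            raise ManifestError(f"manifest missing mandatory key {key!r}")

    if "files" not in cp or not cp["files"]:
        raise ManifestError("manifest missing a non-empty [files] section")
    files: list[tuple[str, str]] = []
    for key, location in cp["files"].items():
        role = key.rstrip("0123456789")
        if role not in MANIFEST_ROLES:
            raise ManifestError(
                f"unknown file role {key!r}; expected one of {MANIFEST_ROLES}"
            )
        files.append((role, location))

    return DatawrapManifest(
        description=pkg["description"],
        version=pkg["version"],
        maintainer=pkg["maintainer"],
        species=section["species"],
        kind=kind,
        name=section["name"],
        files=files,
    )


def write_manifest(manifest: DatawrapManifest) -> str:
    cp = configparser.ConfigParser()
    cp["package"] = {
        "description": manifest.description,
        "version": manifest.version,
        "maintainer": manifest.maintainer,
    }
    section = "genome" if manifest.kind == "genome" else "snps"
    cp[section] = {"name": manifest.name, "species": manifest.species}
    counts: dict[str, int] = {}
    cp["files"] = {}
    for role, path in manifest.files:
        n = counts.get(role, 0)
        counts[role] = n + 1
        cp["files"][role if n == 0 else f"{role}{n + 1}"] = path
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# FASTA


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


def parse_fasta(stream) -> list[FastaRecord]:
    """One record per ``>`` header; sequence upper-cased, whitespace joined."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[FastaRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is not None:
            rid, _, desc = header.partition(" ")
            records.append(FastaRecord(rid, desc.strip(), "".join(chunks).upper()))

    for lineno, raw in enumerate(stream, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise FormatError(
                    f"FASTA line {lineno}: sequence before first '>' header"
                )
            chunks.append("".join(line.split()))
    flush()
    return records


def write_fasta(records, width: int = 70) -> str:
    out = []
    for rec in records:
        rid = rec.id if hasattr(rec, "id") else rec[0]
        seq = rec.sequence if hasattr(rec, "sequence") else rec[1]
        out.append(f">{rid}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# GTF (Ensembl GFF2 attribute dialect)


@dataclass(frozen=True)
class GtfFeature:
    """One annotation line, with internal 0-based half-open coordinates."""

    chrom: str
    source: str
    feature: str
    start: int                      # 0-based inclusive
    end: int                        # exclusive
    score: str
    strand: str
    frame: str
    attributes: dict[str, str]


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(stream) -> list[GtfFeature]:
    """Parse tab-separated 9-column GTF; ``#`` comment lines are skipped.

    1-based inclusive coordinates become internal 0-based half-open.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    features: list[GtfFeature] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(
                f"GTF line {lineno}: expected 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        chrom, source, feature, start_s, end_s, score, strand, frame, attrs = cols
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"GTF line {lineno}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        if end1 < start1:
            raise CoordinateError(f"GTF line {lineno}: end {end1} < start {start1}")
        features.append(
            GtfFeature(
                chrom=normalize_chrom(chrom),
                source=source,
                feature=feature,
                start=start1 - 1,
                end=end1,
                score=score,
                strand=strand,
                frame=frame,
                attributes=_parse_gtf_attributes(attrs),
            )
        )
    return features


def write_gtf(features) -> str:
    """Export features back to 1-based inclusive GTF text."""
    lines = []
    for f in features:
        attrs = " ".join(f'{k} "{v}";' for k, v in f.attributes.items())
        lines.append(
            "\t".join(
                (
                    f.chrom, f.source, f.feature,
                    str(f.start + 1), str(f.end),
                    f.score, f.strand, f.frame, attrs,
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' prefix so FASTA/GTF/VCF names cross-match."""
    return name[3:] if name.lower().startswith("chr") and len(name) > 3 else name


# ---------------------------------------------------------------------------
# VCF


@dataclass(frozen=True)
class VcfVariant:
    """One normalized ALT of one VCF line.

    ``position`` is internal 0-based.  For substitutions and deletions it
    is the first affected reference base; for insertions it is the base
    *after which* the inserted sequence goes (the VCF anchor base).
    """

    chromosome: str
    position: int
    ref_allele: str                 # "" for insertions
    alt_allele: str                 # "" for deletions
    kind: str                       # substitution | insertion | deletion
    vcf_id: str
    quality: float | None
    filter: str
    info: dict[str, str]


def normalize_alleles(ref: str, alt: str) -> tuple[str, str, int]:
    """Trim shared leading then trailing bases; returns (ref, alt, lead).

    *lead* is how many leading bases were removed (shifts the position).
    Trimming is idempotent: re-normalizing trimmed alleles is the identity
    with lead 0.
    """
    lead = 0
    while ref and alt and ref[0] == alt[0]:
        ref, alt, lead = ref[1:], alt[1:], lead + 1
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return ref, alt, lead


def _classify(ref: str, alt: str, pos0: int):
    """Trim the VCF anchor base(s) and classify the variant."""
    ref, alt, lead = normalize_alleles(ref, alt)
    pos0 += lead
    if len(ref) == 1 and len(alt) == 1:
        return "substitution", ref, alt, pos0
    if not ref and alt:
        # insertion goes after the base preceding the trimmed position
        return "insertion", "", alt, pos0 - 1
    if ref and not alt:
        return "deletion", ref, "", pos0
    if not ref and not alt:
        raise FormatError("VCF record with REF == ALT")
    # multi-base substitution (same length): keep as block substitution?
    # The model is limited to SNP/INDEL; represent as deletion+insertion is
    # ambiguous, so reject.
    raise FormatError(
        f"unsupported complex variant REF={ref!r} ALT={alt!r}"
    )


def _check_bases(allele: str, lineno: int) -> str:
    allele = allele.upper()
    for i, c in enumerate(allele):
        if c not in NUCLEOTIDE_ALPHABET or c == "-":
            raise AlphabetError(c, i, f"VCF line {lineno} allele {allele!r}")
    return allele


def parse_vcf(stream) -> list[VcfVariant]:
    """Parse a VCF 4.x subset; one variant per ALT of each record line."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    variants: list[VcfVariant] = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise FormatError(
                f"VCF line {lineno}: expected >= 8 columns, got {len(cols)}"
            )
        chrom, pos_s, vid, ref, alts, qual_s, filt, info_s = cols[:8]
        try:
            pos1 = int(pos_s)
        except ValueError:
            raise FormatError(f"VCF line {lineno}: non-numeric POS {pos_s!r}") from None
        ref = _check_bases(ref, lineno)
        quality = None if qual_s in (".", "") else float(qual_s)
        info = {}
        if info_s not in (".", ""):
            for item in info_s.split(";"):
                k, _, v = item.partition("=")
                info[k] = v
        for alt in alts.split(","):
            if alt in (".", ""):
                continue
            alt = _check_bases(alt, lineno)
            kind, r, a, pos0 = _classify(ref, alt, pos1 - 1)
            variants.append(
                VcfVariant(
                    chromosome=normalize_chrom(chrom),
                    position=pos0,
                    ref_allele=r,
                    alt_allele=a,
                    kind=kind,
                    vcf_id=vid,
                    quality=quality,
                    filter=filt,
                    info=info,
                )
            )
    return variants


# ---------------------------------------------------------------------------
# FASTQ


@dataclass(frozen=True)
class FastqRead:
    id: str
    sequence: str
    quality: str


def parse_fastq(stream) -> list[FastqRead]:
    """Standard 4-line FASTQ groups; truncation or length mismatch errors."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [l.rstrip("\n") for l in stream]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"truncated FASTQ: {len(lines)} lines is not a multiple of 4"
        )
    reads = []
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"FASTQ line {i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"FASTQ line {i + 3}: expected '+' separator")
        if len(seq) != len(qual):
            raise FormatError(
                f"FASTQ read {head[1:]!r}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        reads.append(FastqRead(head[1:].split()[0], seq.upper(), qual))
    return reads


# ---------------------------------------------------------------------------
# CSV


def parse_csv(stream, delimiter: str = ",") -> list[dict[str, str]]:
    """First row is the header; returns one dict per data row."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = _csv.DictReader(stream, delimiter=delimiter)
    return [dict(row) for row in reader]
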