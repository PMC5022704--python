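"""Datawrap ingestion: populate the store from packaged data archives.

A *datawrap* is a tar.gz archive or a plain directory holding a
``manifest.ini`` plus the data files it names: chromosome FASTA and an
Ensembl-style GTF for a reference genome, or a VCF / dbSNP-like
tab-delimited variant table for a polymorphism set.  Importing is the
only way data enters the store.

Reference import persists the whole hierarchy (genome, chromosomes with
sequences, genes, transcripts, exons, proteins), computes each
transcript's reference spliced/CDS sequence and protein, and refuses to
finish unless the hierarchy validates cleanly.
"""

from __future__ import annotations

import logging
import tarfile
from pathlib import Path

from .errors import DatawrapImportError, FormatError, ManifestError
from .model import validate_hierarchy
from .parsers import (
    DatawrapManifest,
    is_remote,
    normalize_chrom,
    parse_csv,
    parse_fasta,
    parse_gtf,
    parse_manifest,
    parse_vcf,
    VcfVariant,
    _classify,
)
from .sequence import normalize, reverse_complement, translate

logger = logging.getLogger(__name__)


class DatawrapReader:
    """Uniform text access to a datawrap directory or tar.gz archive."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        if not self.path.exists():
            raise DatawrapImportError(f"datawrap {self.path} does not exist")
        self._tar = None
        if self.path.is_file():
            try:
                self._tar = tarfile.open(self.path, "r:*")
            except tarfile.TarError as e:
                raise DatawrapImportError(
                    f"{self.path} is neither a directory nor a tar archive: {e}"
                ) from e

    def read_text(self, member: str) -> str:
        if self._tar is not None:
            names = {Path(n).as_posix(): n for n in self._tar.getnames()}
            # allow a single leading directory component inside the archive
            candidates = [member] + [
                n for n in names if n.endswith("/" + member)
            ]
            for cand in candidates:
                if cand in names:
                    f = self._tar.extractfile(names[cand])
                    if f is not None:
                        return f.read().decode()
            raise DatawrapImportError(
                f"member {member!r} missing from archive {self.path}"
            )
        p = self.path / member
        if not p.exists():
            raise DatawrapImportError(f"file {member!r} missing from {self.path}")
        return p.read_text()

    def manifest(self) -> DatawrapManifest:
        try:
            text = self.read_text("manifest.ini")
        except DatawrapImportError:
            raise ManifestError(f"no manifest.ini in datawrap {self.path}")
        return parse_manifest(text)

    def close(self):
        if self._tar is not None:
            self._tar.close()


def _local_paths(manifest: DatawrapManifest, role: str) -> list[str]:
    paths = [p for p in manifest.paths(role) if not is_remote(p)]
    remote = [p for p in manifest.paths(role) if is_remote(p)]
    if remote and not paths:
        raise DatawrapImportError(
            f"all {role!r} files in manifest are remote URLs; offline import "
            f"needs at least one packaged file ({remote})"
        )
    return paths


# ---------------------------------------------------------------------------
# genome import


def import_genome(store, datawrap_path, force: bool = False) -> str:
    """Import a reference-genome datawrap; returns the genome name."""
    reader = DatawrapReader(datawrap_path)
    try:
        manifest = reader.manifest()
        if manifest.kind != "genome":
            raise ManifestError(
                f"expected a genome datawrap, got {manifest.kind!r}"
            )
        fasta_paths = _local_paths(manifest, "fasta")
        gtf_paths = _local_paths(manifest, "gtf")
        if not fasta_paths or not gtf_paths:
            raise ManifestError(
                "genome datawrap needs at least one fasta and one gtf entry"
            )

        name = manifest.name
        existing = list(store.get("Genome", {"id": name}))
        if existing:
            if not force:
                raise DatawrapImportError(
                    f"genome {name!r} already imported; use force to replace"
                )
            _drop_genome(store, name)

        chromosomes: dict[str, str] = {}
        for path in fasta_paths:
            for rec in parse_fasta(reader.read_text(path)):
                cname = normalize_chrom(rec.id)
                if cname in chromosomes:
                    raise DatawrapImportError(
                        f"chromosome {cname!r} appears twice in FASTA input"
                    )
                chromosomes[cname] = normalize(rec.sequence, f"chromosome {cname}")

        features = []
        for path in gtf_paths:
            features.extend(parse_gtf(reader.read_text(path)))

        unmatched = sorted(
            {f.chrom for f in features} - set(chromosomes)
        )
        if unmatched:
            raise DatawrapImportError(
                f"GTF references chromosomes absent from FASTA: {unmatched}"
            )

        _persist_genome(store, manifest, chromosomes, features)
        violations = validate_hierarchy(store, name)
        if violations:
            store.connection.rollback()
            raise DatawrapImportError(
                "imported genome fails validation: "
                + "; ".join(str(v) for v in violations)
            )
        store.commit()
        logger.info("imported genome %s (%d chromosomes, %d features)",
                    name, len(chromosomes), len(features))
        return name
    finally:
        reader.close()


def _drop_genome(store, name: str) -> None:
    store.delete_where("Genome", {"id": name})
    for kind in ("Chromosome", "Gene", "Transcript", "Exon", "Protein"):
        store.delete_where(kind, {"genome": name})


def _persist_genome(store, manifest, chromosomes, features) -> None:
    name = manifest.name
    store.insert(
        "Genome",
        {
            "id": name,
            "species": manifest.species,
            "description": manifest.description,
            "version": manifest.version,
            "maintainer": manifest.maintainer,
            "chromosome_names": sorted(chromosomes),
        },
    )
    store.insert_many(
        "Chromosome",
        [
            {
                "id": f"{name}/{cname}",
                "genome": name,
                "name": cname,
                "length": len(seq),
                "sequence": seq,
            }
            for cname, seq in sorted(chromosomes.items())
        ],
    )

    genes: dict[str, dict] = {}
    transcripts: dict[str, dict] = {}
    exons: dict[str, dict] = {}
    cds_by_tx: dict[str, list] = {}

    for f in features:
        attrs = f.attributes
        gid = attrs.get("gene_id")
        tid = attrs.get("transcript_id")
        if f.feature == "gene":
            if gid is None:
                raise FormatError("gene feature without gene_id attribute")
            genes[gid] = {
                "id": gid,
                "genome": name,
                "name": attrs.get("gene_name", gid),
                "chromosome": f.chrom,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
            }
        elif f.feature == "transcript":
            if tid is None or gid is None:
                raise FormatError("transcript feature without ids")
            transcripts[tid] = {
                "id": tid,
                "genome": name,
                "gene": gid,
                "chromosome": f.chrom,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "protein_id": attrs.get("protein_id"),
            }
        elif f.feature == "exon":
            if tid is None:
                raise FormatError("exon feature without transcript_id")
            eid = attrs.get("exon_id") or f"{tid}.e{attrs.get('exon_number', '?')}"
            exons[eid] = {
                "id": eid,
                "genome": name,
                "gene": gid,
                "transcript": tid,
                "chromosome": f.chrom,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
                "rank": int(attrs.get("exon_number", 0)),
            }
        elif f.feature == "CDS":
            if tid is None:
                raise FormatError("CDS feature without transcript_id")
            cds_by_tx.setdefault(tid, []).append(f)

    # derive missing gene/transcript records from their exons
    for eid, e in exons.items():
        if e["transcript"] not in transcripts:
            t = transcripts.setdefault(
                e["transcript"],
                {
                    "id": e["transcript"], "genome": name, "gene": e["gene"],
                    "chromosome": e["chromosome"], "start": e["start"],
                    "end": e["end"], "strand": e["strand"], "protein_id": None,
                },
            )
            t["start"] = min(t["start"], e["start"])
            t["end"] = max(t["end"], e["end"])
    for tid, t in transcripts.items():
        if t["gene"] not in genes:
            g = genes.setdefault(
                t["gene"],
                {
                    "id": t["gene"], "genome": name, "name": t["gene"],
                    "chromosome": t["chromosome"], "start": t["start"],
                    "end": t["end"], "strand": t["strand"],
                },
            )
            g["start"] = min(g["start"], t["start"])
            g["end"] = max(g["end"], t["end"])

    # strand consistency: exons/transcripts inherit the gene strand
    for t in transcripts.values():
        if t["strand"] != genes[t["gene"]]["strand"]:
            raise DatawrapImportError(
                f"transcript {t['id']} strand {t['strand']} differs from "
                f"gene {t['gene']}"
            )
    for e in exons.values():
        if e["strand"] != transcripts[e["transcript"]]["strand"]:
            raise DatawrapImportError(
                f"exon {e['id']} strand differs from transcript {e['transcript']}"
            )

    # per-transcript assembly: reference sequences, CDS intervals, proteins
    proteins = []
    for tid, t in transcripts.items():
        tx_exons = sorted(
            (e for e in exons.values() if e["transcript"] == tid),
            key=lambda e: e["start"],
        )
        if not tx_exons:
            raise DatawrapImportError(f"transcript {tid} has no exons")
        t["exon_ids"] = [e["id"] for e in tx_exons]
        cds_feats = sorted(cds_by_tx.get(tid, []), key=lambda f: f.start)
        t["cds_intervals"] = [[f.start, f.end] for f in cds_feats]
        if cds_feats:
            first = cds_feats[0] if t["strand"] == "+" else cds_feats[-1]
            t["cds_frame"] = int(first.frame) if first.frame.isdigit() else 0
        else:
            t["cds_frame"] = 0

    # fill rank defaults where exon_number was absent
    for tid, t in transcripts.items():
        tx_exons = sorted(
            (e for e in exons.values() if e["transcript"] == tid),
            key=lambda e: e["start"],
        )
        ordered = tx_exons if t["strand"] == "+" else tx_exons[::-1]
        for i, e in enumerate(ordered, 1):
            if e["rank"] == 0:
                e["rank"] = i

    chrom_seqs = {c: s for c, s in chromosomes.items()}
    for tid, t in transcripts.items():
        seq = _assemble(chrom_seqs[t["chromosome"]],
                        [(exons[eid]["start"], exons[eid]["end"])
                         for eid in t["exon_ids"]],
                        t["strand"])
        cds = _assemble(chrom_seqs[t["chromosome"]],
                        [tuple(iv) for iv in t["cds_intervals"]],
                        t["strand"])
        if t["cds_frame"]:
            cds = cds[t["cds_frame"]:]
        t["sequence"] = seq
        t["cds_sequence"] = cds
        if t["cds_intervals"]:
            pid = t["protein_id"] or f"{tid}_prot"
            t["protein_id"] = pid
            proteins.append(
                {
                    "id": pid,
                    "genome": name,
                    "transcript": tid,
                    "sequence": translate(cds, "truncate_at_stop"),
                }
            )

    store.insert_many("Gene", list(genes.values()))
    store.insert_many("Transcript", list(transcripts.values()))
    store.insert_many("Exon", list(exons.values()))
    store.insert_many("Protein", proteins)


def _assemble(chrom_seq: str, intervals, strand: str) -> str:
    parts = [chrom_seq[s:e] for (s, e) in sorted(intervals)]
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# polymorphism import


def import_polymorphisms(store, datawrap_path, force: bool = False) -> str:
    """Import a polymorphism-set datawrap; returns the set name."""
    reader = DatawrapReader(datawrap_path)
    try:
        manifest = reader.manifest()
        if manifest.kind != "snps":
            raise ManifestError(
                f"expected a polymorphism datawrap, got {manifest.kind!r}"
            )
        snp_paths = _local_paths(manifest, "snp")
        if not snp_paths:
            raise ManifestError("polymorphism datawrap needs a snp file entry")

        name = manifest.name
        if list(store.get("SnpSet", {"id": name})):
            if not force:
                raise DatawrapImportError(
                    f"polymorphism set {name!r} already imported; "
                    f"use force to replace"
                )
            store.delete_where("SnpSet", {"id": name})
            store.delete_where("Polymorphism", {"set_name": name})

        rows = []
        counter = 0
        for path in snp_paths:
            text = reader.read_text(path)
            variants = (
                parse_vcf(text)
                if _looks_like_vcf(path, text)
                else _parse_dbsnp_table(text)
            )
            for v in variants:
                counter += 1
                metadata = {"filter": v.filter, "vcf_id": v.vcf_id}
                metadata.update(v.info)
                rows.append(
                    {
                        "id": f"{name}:{counter:06d}",
                        "set_name": name,
                        "chromosome": v.chromosome,
                        "position": v.position,
                        "ref_allele": v.ref_allele,
                        "alt_allele": v.alt_allele,
                        "variant_kind": v.kind,
                        "quality": v.quality,
                        "metadata": metadata,
                    }
                )

        store.insert(
            "SnpSet",
            {
                "id": name,
                "species": manifest.species,
                "description": manifest.description,
                "version": manifest.version,
                "maintainer": manifest.maintainer,
            },
        )
        store.insert_many("Polymorphism", rows)
        store.commit()
        logger.info("imported polymorphism set %s (%d records)", name, len(rows))
        return name
    finally:
        reader.close()


def _looks_like_vcf(path: str, text: str) -> bool:
    if path.endswith(".vcf"):
        return True
    head = text.lstrip()[:64]
    return head.startswith("##fileformat=VCF") or head.startswith("#CHROM")


def _parse_dbsnp_table(text: str) -> list[VcfVariant]:
    """dbSNP-like tab-delimited dialect.

    Header columns consumed: ``chromosome``, ``position`` (1-based),
    ``ref``, ``alt`` (comma-separated alternates), ``validated``
    (optional truthy flag), ``quality`` (optional float); everything else
    is ignored.
    """
    out = []
    for row in parse_csv(text, delimiter="\t"):
        try:
            pos1 = int(row["position"])
        except (KeyError, ValueError):
            raise FormatError(
                f"dbSNP table row with missing/non-numeric position: {row}"
            ) from None
        quality = float(row["quality"]) if row.get("quality") else None
        validated = row.get("validated", "")
        for alt in row.get("alt", "").split(","):
            if not alt:
                continue
            kind, r, a, pos0 = _classify(
                row["ref"].upper(), alt.upper(), pos1 - 1
            )
            out.append(
                VcfVariant(
                    chromosome=normalize_chrom(row["chromosome"]),
                    position=pos0,
                    ref_allele=r,
                    alt_allele=a,
                    kind=kind,
                    vcf_id=row.get("id", "."),
                    quality=quality,
                    filter="PASS" if validated.lower() in
                           ("1", "true", "yes", "y") else ".",
                    info={"validated": validated} if validated else {},
                )
            )
    return out
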