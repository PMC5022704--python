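# genovault

An embedded, lazily-loading genome/proteome exploration library for
precision-medicine scripting.  genovault imports reference annotations
(chromosome FASTA + Ensembl-style GTF) and polymorphism sets (VCF or
dbSNP-like tables) from packaged *datawraps* into a single-file SQLite
store, serves every record — genomes, chromosomes, genes, transcripts,
exons, proteins, polymorphisms — through one lazy `get()` query
interface, and materializes **variant-personalized** transcript and
protein sequences through user-defined allele filters.

It is aimed at people who need subject-specific sequences inside a
Python pipeline — e.g. building customized protein databases for
proteogenomic peptide identification — without a genome browser, a
server, or remote API calls.

## The core computation

A personalized genome is a triple *(reference R, polymorphism sets
P₁…Pₖ, allele filter f)*.  For a transcript with exon intervals
*e₁ < … < eₙ* on chromosome sequence *S* (0-based, half-open
coordinates), the personalized sequence is

```
t = op_strand( concat_i  edit( S[e_i],  f(loci(P, e_i)) ) )
```

where `loci` groups all variants overlapping the interval by position,
the filter `f` maps each locus's candidates to one decision — keep
reference, substitute one base, insert after the anchor, or delete *L*
bases — `edit` applies the retained, non-overlapping decisions in
descending position order (equivalent to editing a position-tagged
character list, so indel shifts never corrupt coordinates), and
`op_strand` is the identity (+) or reverse complement (−).  The protein
is `translate(t_CDS)` under the standard genetic code, truncated at the
first stop.

The default filter preserves heterozygosity: a substitution locus with
reference A and alternate G is encoded as the IUPAC code R, and an
ambiguous codon translates to the unique amino acid if all its
expansions agree, else to `X`.  Indels are applied only when validated
(VCF `FILTER PASS`).  Everything is lazy: nothing heavier than record
headers is read until a sequence is actually accessed, loaded records
are session singletons, and several personalized genomes share one
in-memory copy of the reference.

## Worked example

No downloads are needed: the `fixtures` module generates toy datawraps
with planted, independently-computed ground truth.

```python
from pathlib import Path
from genovault import (Store, PersonalizedGenome,
                       import_genome, import_polymorphisms)
from genovault.fixtures import (FixtureSpec, VariantSpec,
                                generate_genome_datawrap,
                                generate_variant_datawrap)

work = Path("example")
genome_wrap, truth = generate_genome_datawrap(FixtureSpec(), work / "toy-genome")
snp_wrap, _ = generate_variant_datawrap(VariantSpec(), truth, work / "toy-snps")

store = Store(work / "genovault.db")
import_genome(store, genome_wrap)          # 1 x 10 kb chromosome, 2 genes,
import_polymorphisms(store, snp_wrap)      # 3 transcripts, 7 exons, 6 variants

pg = PersonalizedGenome(store, "toy-genome", ["toy-snps"])
for protein in store.get("Protein", {}):
    ref, per = protein.sequence, pg.protein_sequence(protein.id)
    diffs = [i + 1 for i, (a, b) in enumerate(zip(ref, per)) if a != b]
    print(f"{protein.id}: {len(ref)} aa -> {len(per)} aa, "
          f"changed residues: {diffs if diffs else 'none'}")
print(pg.export_fasta(["TX001.1_prot"], kind="protein"), end="")
```

prints

```
TX001.1_prot: 48 aa -> 25 aa, changed residues: [11, 12, 13, 14, 15, 17, 18, 19, 20, 21, 22, 23, 24, 25]
TX001.2_prot: 89 aa -> 66 aa, changed residues: [4, 5, 6, 7, 8, 9, 10, ...]
TX002.1_prot: 61 aa -> 61 aa, changed residues: none
>TX001.1_prot|toy-genome|toy-snps
RKNQQLQWRVNTATAATNGACMKSA
```

The planted 3 bp deletion and 2 bp insertion frameshift the two plus-
strand transcripts — downstream residues change and a new stop shortens
both proteins — while the minus-strand transcript's multi-allelic SNP is
IUPAC-encoded in its cDNA but happens to be synonymous at the protein
level.  Note that `pg.protein_sequence` only loaded the one chromosome
sequence it needed, once; constructing `pg` loaded nothing.

The same operations are scriptable from a shell:

```sh
genovault --store my.db bootstrap list
genovault --store my.db bootstrap install toy-genome
genovault --store my.db import-snps toy-snps.datawrap
genovault --store my.db sequence --genome toy-genome --snps toy-snps \
          --filter het-iupac --kind protein TX001.1_prot
genovault --store my.db index ensure Transcript id
genovault --store my.db validate toy-genome
```

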