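# mockmap

**Mock-community metagenomic read mapping and profiling.**

Shotgun metagenomics characterises a microbial community by aligning its
reads against a database of reference genomes and summarising the
alignments into per-organism abundance. How that summary behaves depends on
decisions that are easy to get wrong: how redundant reference genomes are
pruned, which similarity and length filters the aligner applies, and —
critically — what is done with reads that align equally well to several
genomes. `mockmap` implements the whole pipeline as a tested, self-contained
toolkit, together with a mock-community simulator that provides per-read
ground truth, so every design choice can be measured rather than assumed.

It is intended for people building or validating metagenomic profiling
pipelines: it will not replace a production aligner on terabases of data,
but it reproduces the *behaviour* of the standard operating procedure at
benchable scale, with exact truth labels.

## What it computes

For each strain *g* with total genome length *L<sub>g</sub>* (chromosome +
plasmids) and per-base coverage *c<sub>i</sub>* accumulated from aligned
reference spans:

- **breadth** = 100 · |{i : c<sub>i</sub> ≥ 1}| / L<sub>g</sub> (percent of
  bases covered at least once);
- **depth** = Σ<sub>i</sub> c<sub>i</sub> / L<sub>g</sub> (mean coverage, x);
- a strain is **detected** when breadth ≥ 1% and depth ≥ 0.01x (both
  inclusive).

Reads are mapped by a seed-and-extend aligner (16-mer seeds, local
dynamic-programming extension; match +1, mismatch −2, gap −3 opening and −1
per extra column) and reported only when they pass two CLC-style filters:
identity ≥ `-s` within the aligned region and aligned query fraction ≥ `-l`
(recommended: `-s 0.80 -l 0.75`). All placements tied at the best score form
a read's *hit set*; ties are resolved under one of four strategies:
**top-random** (one tie chosen uniformly, MAPQ 0), **unique-only** (tied
reads suppressed), **topN** (all ties reported if ≤ N, else none) and
**all-hits**.

Upstream, reference databases are strain-prefixed, dereplicated within each
species by genome-wide identity (estimated from canonical k-mer containment
C as 1 + ln C / k) at a 0.90 threshold (0.83 relaxed), with protected
strains always retained and plasmids restored. Reads are screened with a
DUST-style trinucleotide complexity filter; when one mate of a pair is
removed, the survivor is orphaned into the fragment set and still mapped.

## Worked example

Simulate a four-strain community at concentrations 8:4:2:1 with 1%
sequencing error, map it back to its own reference, resolve ties at random,
and profile:

```python
import numpy as np
from mockmap import (
    CommunitySpec, build_index, classify_fates, compute_coverage,
    apply_detection, map_pairs, resolve, rollup, simulate_community,
    spearman_rank,
)
from mockmap.refdb import ReferenceDB, StrainRecord

rng = np.random.default_rng(42)
def rand_seq(n): return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

genera = ["Deinobacter", "Acinetomimus", "Staphylomimus", "Helicomimus"]
strains, seqs = [], {}
for i, g in enumerate(genera):
    p = f"S{i}"
    seqs[f"{p}_chr"] = rand_seq(20_000)
    strains.append(StrainRecord(prefix=p, strain_name=f"{g} strain {i}",
                                species=f"sp{i}", genus=g,
                                sequence_ids=[f"{p}_chr"], chromosome_length=20_000))
db = ReferenceDB(strains=strains, sequences=seqs)

spec = CommunitySpec(members=[("S0", 8.0), ("S1", 4.0), ("S2", 2.0), ("S3", 1.0)],
                     n_pairs=3000, substitution_rate=0.01, seed=1)
sim = simulate_community(db, spec)
index = build_index(db)
hitsets, report = map_pairs(sim.pairs, [], index, db,
                            min_length_fraction=0.75, min_similarity=0.80)
placements = resolve(hitsets, "top_random", seed=7)
stats = apply_detection(compute_coverage(placements, db))
table = rollup(stats, db, level="genus")
print(table[["taxon", "breadth_pct", "depth_x", "detected",
             "relative_abundance"]].round(3).to_string(index=False))
fates = classify_fates(placements, sim.truth, db, level="strain")
print(f"correct strain: {fates.correct_strain}/{fates.total}")
rho = spearman_rank([8.0, 4.0, 2.0, 1.0], [s.depth for s in stats])
print(f"Spearman rho (concentration vs depth): {rho:.3f}")
```

Output:

```
        taxon  breadth_pct  depth_x  detected  relative_abundance
  Deinobacter       99.850   16.300      True               0.544
 Acinetomimus       99.940    7.650      True               0.255
Staphylomimus       98.520    3.956      True               0.132
  Helicomimus       88.515    2.057      True               0.069
correct strain: 6000/6000
Spearman rho (concentration vs depth): 1.000
```

Depths track the 8:4:2:1 concentrations (16.3x ≈ 2 × 7.65x ≈ 4 × 3.96x), the
rank correlation with the true concentrations is perfect, and with every
strain unique in the database all 6,000 reads land on their source strain
despite the 1% error rate. The least abundant strain at ~2x already shows
breadth dropping below 90% — uncovered gaps, not mapping failures.

The same pipeline is available from the shell:

```
mockmap simulate --fasta ref.fasta --index ref.tsv --spec community.yaml --out sim --seed 42
mockmap screen   --pairs sim_1.fastq sim_2.fastq --frags sim_frag.fastq --out scr
mockmap align    --fasta ref.fasta --index ref.tsv --pairs scr_1.fastq scr_2.fastq \
                 --frags scr_frag.fastq -l 0.75 -s 0.80 --out aln.sam
mockmap profile  --fasta ref.fasta --index ref.tsv --sam aln.sam --out profile.tsv
mockmap evaluate --fasta ref.fasta --index ref.tsv --truth sim.truth.tsv \
                 --sam aln.sam --out fates.json
```

External SAM (from any aligner) can enter the pipeline through
`mockmap resolve` / `mockmap profile` as long as its references match the
database.

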