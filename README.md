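# attrace

Detection of **active, excisable prophages** in bacterial and archaeal
genomes from short-read alignments, using **overlapping split-read
alignments** of the attachment sites.

## The problem and the signal

A temperate phage integrates into its host chromosome between two
copies of its attachment-site core: `attL … prophage … attR`, where
attL and attR are direct repeats sharing a common core of 2–150 bp.
When the prophage excises, the chromosome retains a single core
(**attB**) and the circularised phage carries the other (**attP**).
In a sequencing library of a lysogen culture, a small fraction of
molecules are excised or circular, and any 2×150 bp read spanning one
of those junctions aligns to the reference in **two pieces whose query
intervals overlap**: with piece one spanning read positions R1–R2 and
piece two R3–R4,

```
R1 < R3 < R2 < R4,     overlap = R2 − R3 + 1 = att core length
```

because the att core at the junction matches both the attL and the attR
locus. This single geometric criterion separates true excision
junctions from the background of soft-clipped alignment noise, needs as
little as one read, and pins all four att endpoints exactly:

* attB evidence: prefix piece ends at `attL_end`, suffix piece starts at
  `attR_start`;
* attP evidence: prefix piece ends at `attR_end`, suffix piece starts at
  `attL_start`.

The reported prophage **size** is `attR_start − attL_start` and the
**att length** is `attL_end − attL_start + 1`.

The pipeline: extract candidate split reads and discordant pairs from a
SAM stream by clip-pattern + FLAG rules → verify each candidate by
local re-alignment and the overlap criterion → classify attB/attP →
cluster by the four endpoints → merge discordant pairs as secondary
evidence → filter (att length > 2 bp, 5 kb < size < 150 kb, ≥ 1 attB
and ≥ 1 attP event by default) → report. Draft assemblies are handled
in contig mode, including prophages split across two contigs in any
relative orientation. A simulator generates host/excised/circular
molecule mixtures with truth alignments, and a fold-change estimator
compares excision between conditions from normalised junction-read
counts.

## Worked example

```bash
# simulate a 100 kb lysogen genome, 20 kb prophage, 30 bp att core,
# molecule ratios WT:excised:circular = 2:1:1 at 60x coverage
attrace simulate --out sim --genome-len 100000 --att-len 30 \
    --prophage-size 20000 --ratios 2,1,1 --depth 60 --error-rate 0 --seed 7

# detect
attrace trace --sam sim/truth.sam --fasta sim/reference.fasta --out run
```

`run/prophages.tsv` (one row per candidate):

```
prophage  contig  attL_start  attL_end  attR_start  attR_end  size   att_length  SR_attB  SR_attP  DRP_attB  DRP_attP
P1        chr     12667       12696     32667       32696     20000  30          12       15       2         7
```

Read it as: one prophage on `chr`, attL at 12,667–12,696 and attR at
32,667–32,696 (a 30 bp core), spanning 20,000 bp; 12 split reads
support the excision (attB) junction and 15 the circular (attP)
junction, plus 2 and 7 discordant pairs — the simulation's true att
quad, recovered exactly. `run/evidence.txt` lists each supporting
read's two alignment pieces for manual review of genes disrupted at the
integration site, and `run/run_summary.json` the per-stage counts.

```bash
attrace evaluate --report run/prophages.tsv --manifest sim/manifest.json
# {"hit": true, "n_calls": 1}
```

For two conditions of one strain, `attrace foldchange` pairs candidates
across the two reports and prints the excision fold-change from
evidence counts normalised by library size (a zero count entering a
dividend is replaced by one and flagged), plus qPCR primer target
windows (BED) around the attB/attP junctions.

Python API: `attrace.run_trace_records`, `attrace.simulate_prophage_genome`,
`attrace.fold_change`, … mirror the CLI.

## Contig-level output

Candidates whose attL and attR fall on two different contigs are
written to `prophages_cross_contig.tsv` with per-contig att
coordinates, the relative orientation class, an *approximate* size
(exact when the contigs abut, an underestimate when sequence
intervenes) and a junction annotation — `contig1 = ::contig2` means the
prophage runs off the right end of contig1 into the left end of
contig2 (`=` marks a junction-facing contig end). Whether a
cross-contig jump is the excision or the circularisation junction is
decided by which interpretation implies a plausible prophage span;
undecidable evidence is counted as ambiguous.

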