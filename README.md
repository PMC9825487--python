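# uorfkit

Identification, classification and annotation of **upstream open reading
frames (uORFs)** from ribosome-profiling (Ribo-seq) data.

uORFs are start-to-stop ORFs whose start codon lies in an mRNA's 5′UTR,
upstream of the main coding sequence (CDS).  They regulate translation of
the downstream CDS, and mutations that create or destroy them are linked to
disease.  `uorfkit` provides, as a Python library with a thin command-line
interface:

- **Candidate enumeration** — all start-to-stop ORFs beginning in the 5′UTR,
  using ATG and the four most used near-cognate starts (CTG/GTG/TTG/ACG) and
  the three stops (TAG/TGA/TAA), minimum 18 nt of coding sequence (six amino
  acids).  Candidates are classified as *non-overlapping* (stop at or before
  the CDS start), *overlapping out-of-frame*, or *N-terminal extension*
  (in frame, sharing the CDS stop); ORFs entirely inside the CDS are never
  uORFs.  Peptides are translated (near-cognate starts yield initiator Met)
  and Kozak context is classed as strong `[AG]NNATGG`, moderate `[AG]NNATGN`
  / `NNNATGG`, or weak `NNNATGN`.
- **Ribo-seq I/O** — collapsed FASTA (`>seq1_x160` encodes multiplicity),
  BAM/SAM in transcript or genome space (soft-clipped reads and multimappers
  excluded), or a plain P-site TSV; P-site offsets are estimated per read
  length from CDS-start anchoring and applied to 5′ ends, with reads filtered
  to 27–32 nt by default.
- **Quality control** — three admission gates per library: collapsed-FASTA
  size (> 5 Mb, or a read-count floor in memory), RPF length distribution
  (≥ 90% within 26–34 nt, modal length in 27–32 nt), and frame preference
  (frame 0 modal **and** strictly > 50% of CDS P-sites), plus a
  5′UTR/CDS/3′UTR metagene profile.
- **Active-translation calling** — per candidate uORF, the in-frame P-site
  fraction `f0u` (tested against p = 1/3 with an upper-tail exact binomial
  test) and the percentage of maximum entropy (PME) of per-codon coverage
  combine into a score `f0u × PME ∈ [0, 1]`; calls are active at score ≥ 0.5
  (default) with a significant periodicity test and ≥ 10 P-sites.  Among
  active uORFs sharing a stop codon, a representative is selected: the
  5′-most AUG start, advancing downstream when no P-site falls between
  consecutive starts.  Identical uORFs across isoforms are collapsed; calls
  aggregate across samples.
- **5′UTR variant annotation** — variants from a VCF are projected onto
  transcripts and classified by re-enumerating ORFs on the mutated sequence:
  `uAUG_gained`, `uSTART_lost`, `uSTOP_gained`, `uSTOP_lost`, `uFrameshift`,
  `kozak_changed`, or `no_uorf_effect`.
- **Synthetic data** — transcriptomes with planted uORFs of every category,
  RPF libraries with configurable length distribution / frame periodicity /
  initiation pileup, and VCFs engineered to produce each effect class, all
  with recorded ground truth and byte-reproducible from a single seed.

## Worked example

`examples/call_active_uorfs.py` simulates ten transcripts — five planted
uORFs translated (periodic footprints at 1 P-site/nt, 90% in frame), five
silent (sparse uniform background) — and scores every candidate:

```
uORF id                      n_psites    f0u    PME   score  active  truth
TX0001:12-72:ATG                   60   0.92   0.90    0.82  True    translated
TX0002:38-98:ATG                    3   0.33   0.37    0.12  False   silent
TX0003:71-131:ATG                  60   0.93   0.88    0.82  True    translated
TX0004:67-127:ATG                   2   0.50   0.23    0.12  False   silent
...
5 of 10 candidates called active
```

`n_psites` counts P-sites inside the uORF, `f0u` the fraction in the uORF's
own reading frame, and `PME` how evenly the P-sites cover its codons; the
translated uORFs separate cleanly from the silent ones at the 0.5 score
threshold.  The other example scripts demonstrate candidate discovery
(`discover_candidate_uorfs.py`), the QC gates (`qc_a_library.py`), and
variant-effect annotation (`annotate_5utr_variants.py`).

## Command line

```bash
uorfkit simulate --n-tx 20 --out-dir sim/            # synthetic fixture
uorfkit run --annotation sim/annotation.gtf --genome sim/genome.fa \
            --alignments sim/psites.tsv --output-dir out/
```

`run` executes annotate → candidates → P-sites → QC → call (→ variants with
`--vcf`), halting on a failed QC gate unless `--force` is given, and writes
a manifest recording inputs, parameters and seed.  Per-stage subcommands
(`candidates`, `psites`, `qc`, `call`, `annotate-variants`) expose the same
options; precedence is flag > config file > default.

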