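# fgbkit

Tools for **complex fluorescent genetic barcoding (cFGB)** — tracking up to
48 viable cell clones in parallel by flow cytometry, with an orthogonal
DNA-barcode sequencing readout.

## The problem

Clonal heterogeneity drives treatment failure in leukemia and other
cancers, but deep sequencing of bulk DNA barcodes destroys the cells it
measures. Fluorescent genetic barcoding labels each clone with one
lentiviral vector per *color code*, so clone sizes can be read repeatedly,
in real time, on living cells — and clones of interest re-isolated by
sorting. The complexity of such systems is limited by the number of
spectrally distinguishable labels; cFGB multiplies six fluorescent-protein
combinations (single and pairwise expression of hmAG3, YFP and mChEY) by
eight permutations of a surface-displayed chimeric antigen array (CAAR:
antibody-binding or non-binding variants of HA, cMyc and Thy1.1 tags on a
shared EGFRt membrane anchor):

    48 codes = 6 fluorescent combos x 2^3 CAAR permutations

Every code also carries a unique DNA barcode in the same vector, so flow
cytometry and barcode sequencing (BC-Seq) measure the same clones, and
every event can be classified by thresholding 7 channels: (hmAG3, YFP,
mChEY, HA, cMyc, Thy1.1, EGFRt). EGFRt is positive on all 48 codes and
pre-gates vector-bearing cells.

`fgbkit` implements the full analysis stack around this design:

| module | what it does |
|---|---|
| `fgbkit.registry` | the 48-code combinatorial design, expected marker signatures, DNA barcodes at pairwise Hamming distance ≥ 3 |
| `fgbkit.synthetic` | simulators: replicator dynamics with multinomial passage bottlenecks and fitness-jump mutations; gene-marking under silencing and DHFR-addiction selection; event-level cytometry tables (log-normal intensities, debris/doublet/dead/dim contamination); barcode-amplicon FASTQ |
| `fgbkit.gating` | automated threshold fitting (2-component Gaussian mixture / density valley / control percentile) and hierarchical deconvolution: scatter → singlet → viability → EGFRt → fluorescent combo → CAAR → code |
| `fgbkit.bcseq` | index demultiplexing, flank-anchored barcode counting with error tolerance, seq-vs-flow concordance ratios |
| `fgbkit.tracking` | clone-size classes (minor ≤ 2%, large > 5%, dominant > 10%), trajectory-pattern taxonomy (extinction / continuous / transient / delayed expansion / persisting), paired-mix R², relative-fitness estimation from log-ratio slopes, perturbagen fold changes |

Clone fractions follow replicator dynamics with drift: per passage,
`f_i ← f_i·w_i / Σ_j f_j·w_j` (relative fitness `w`), then a multinomial
bottleneck of `n` cells models the 1:10 split. Relative fitness is
recovered from data as the exponentiated slope of `log(f_i/f_ref)` versus
passage, which is exact under replicator dynamics.

## Worked example

Simulate a 48-clone competition for 50 passages (bottleneck 10^4 cells,
rare growth-promoting mutations), then read the endpoint with both the
cytometry and the sequencing pipeline:

```python
import pandas as pd
from fgbkit import *
from fgbkit.tracking import classify_trajectories

reg = build_registry(barcode_length=30, seed=1)
initial = pd.Series(1/48, index=reg.bc_ids)
cfg = SimulationConfig(n_cells_at_passage=10_000, n_passages=50,
                       mutation_rate=0.005, seed=7)
traj = simulate_competition(initial, cfg)

end = traj.iloc[-1]
print(size_classes(end).attrs["counts"])
print(classify_trajectories(traj).value_counts().to_dict())

events = generate_events(end, 50_000, MeasurementModel(), reg, seed=8)
thr = fit_thresholds(events, seed=0)
flow = deconvolute(events, thr, reg)
print(flow.n_codes_detected, round(flow.accuracy, 4))

reads = generate_bc_reads(end, 50_000, reg, error_rate=0.01, seed=9)
seq = count_barcodes(reads, reg, sample="end")
print(round(concordance(seq, flow.fractions).median_ratio, 3))
```

Output:

```
{'minor': 45, 'intermediate': 1, 'large': 0, 'dominant': 2}
{'longitudinal_extinction': 41, 'persisting': 6, 'continuous_expansion': 1}
18 0.9992
0.93
```

Fifty passages of drift and rare fitness jumps collapse the initially
even mix: two clones become dominant (> 10 % of coded cells), 41 go
extinct, and the survivors are mostly minor. At the endpoint the gating
detects the 18 still-present codes and assigns 99.9 % of coded events to
the correct hidden truth label; the BC-Seq counts of the same mix agree
with the flow fractions with a median per-code ratio of 0.93.

The same pipeline is available from the shell:

```bash
fgbkit simulate --seed 1 --out run/ --events 50000 --depth 50000
fgbkit gate     --events run/events.csv --registry run/registry.tsv --out gated/
fgbkit bccount  --fastq run/reads.fastq --registry run/registry.tsv --out counts/
fgbkit track    --trajectory run/trajectory.tsv --reference-code 1 --out report/
fgbkit report   --flow gated/fractions.tsv --seq counts/bc_counts.tsv --out conc/
```

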