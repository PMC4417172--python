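# pausekit

Analysis toolkit for **promoter-proximal RNA polymerase II pausing**: after
initiating transcription, Pol II halts 20–60 nt downstream of the
transcription start site (TSS) and waits there before productive
elongation. `pausekit` implements the computational side of a
multi-assay characterization of this state in human cells, for
genomicists who want to locate pause sites, quantify how occupied a
promoter is, and measure how long individual polymerases stay paused.

Four assays, one package:

- **Short capped RNA (scRNA) sequencing** — the nascent RNA held by a
  paused polymerase. Its 5′ end marks the TSS; its 3′ end marks the pause
  position. `pausekit` refines annotated TSSs to the position with the most
  scRNA 5′-end support within ±500 nt, histograms 3′-end (pause) offsets,
  re-centers metagene profiles on the called TSSs, and profiles divergent
  (antisense) transcription upstream.
- **Paired-end Pol II ChIP sequencing** — fragment centers are known
  exactly, so promoter profiles resolve closely spaced peaks. `pausekit`
  scores promoter enrichment, applies a top-fraction gene filter, builds
  strand-mirrored 25-bp-bin metagenes, and detects promoter peaks.
- **Permanganate footprinting** — KMnO₄ oxidizes unpaired thymines, so the
  transcription bubble of an engaged polymerase appears as a reactive run
  on a sequencing gel. `pausekit` quantifies background-subtracted
  reactivity, calls reactive regions, fits the linear bubble-fraction
  calibration, and converts an activation fold-change `F` (with its
  independent-samples *t*-test) into an occupancy bound: since signal is
  proportional to the occupied fraction and occupancy cannot exceed 100%,
  pre-activation occupancy ≤ 100/F percent.
- **Initiation-block kinetics** — after triptolide blocks TFIIH-dependent
  initiation, paused-polymerase signal decays as 2^(−t/t½). `pausekit`
  fits t½ by log-linear least squares and relates rates to steady-state
  occupancy k_init/(k_init + ln2/t½) under a two-state (vacant ⇄ paused)
  model.

Every input has a synthetic generator (`pausekit.simulate`) with the
statistical structure of the real assays — initiator-like 5′-end jitter,
3′ ends 33–35 nt downstream, antisense reads centered ~150 nt upstream,
twin ChIP fragment-center peaks at the TSS and +110 nt, linear
permanganate response, exponential decay — so the full pipeline runs and
is tested without any sequencing download.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (raw simulated reads land in `scratch/sim/`, summary tables in
`results/`):

```bash
python analysis/01_simulate_data.py
python analysis/02_call_pause_sites.py
python analysis/03_chip_metagene_peaks.py
python analysis/04_footprint_occupancy.py
python analysis/05_pause_half_life.py
```

which prints, among other lines:

```
modal pause offsets: median 34 nt (range 33-35)
metagene sharpness: 0.250 annotated-centered -> 1.000 scRNA-centered over 20 genes
twin promoter peaks at +12.5 and +112.5 nt
reactive region on the uninduced lane: +32..+51 nt
activation fold-change: 2.335 (SD 0.0242, P = 0.0000, n = 6 + 6)
=> pre-activation Pol II occupancy is at most 42.8% (~40%)
pause half-life: 10.13 min (decay rate 0.0684/min, R^2 = 0.9966)
```

Reading the output: scRNA 3′ ends place the pause 33–35 nt downstream of
the start site; re-centering on called TSSs collapses the 5′-end metagene
onto a single-nucleotide spike (sharpness 1.0); ChIP fragment centers
form two peaks (near the TSS and +110 nt) with the pause site *between*
them; the called permanganate-reactive region matches the generated
transcription bubble; a ~2.3-fold reactivity increase on activation caps
the prior occupancy near 40%; and the decay fit recovers the 10-minute
pause half-life.

The same operations are scriptable as a CLI (`pausekit simulate|scrna|
chip|footprint|kinetics ...`); library functions are the primary
interface.

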