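# spotdecode

Spot-based decoding of combinatorially barcoded FISH experiments
(seqFISH-style), with an automated quality-control metric suite and a
synthetic-data benchmark harness.

Given a table of detected fluorescent spots (round, channel, x/y/z,
intensity) and a codebook mapping targets to per-round channel sequences, the
decoder enumerates **every** barcode each spot could participate in, scores
candidates by spatial variance and intensity, and reduces the surviving
candidates to a non-overlapping set of transcript calls via greedy
conflict-graph elimination. Decoding proceeds over an increasing
search-radius schedule, with a strict *filter-first* selection pass followed
by a permissive *decode-first* pass at each radius, consuming spots as they
are used. A `mode` parameter (`high` / `medium` / `low`) trades precision
against recall, and `error_rounds=1` additionally recovers partial barcodes
with one round missing whenever all codebook pairs differ in at least two
rounds.

## Layout

| Module | Purpose |
| --- | --- |
| `spotdecode.core` | Codebook / spot-table types and I/O, Hamming distances, blank (off-target) barcode insertion, pseudoround remapping |
| `spotdecode.decoder` | The candidate-checking decoder: neighbors, enumeration, scoring, selection, support filter, conflict resolution, staged orchestration |
| `spotdecode.qc` | QC metrics: off-target count threshold, per-cell FPR, round/channel tally moments, per-cell count cutoff, Ripley's-K CSR test, scalar ratios, report assembly |
| `spotdecode.smfish` | Threshold-curve utilities: elbow-point selection and normalized Simpson AUC |
| `spotdecode.simulate` | Synthetic spot data with known ground truth, precision/recall evaluation, noise models |
| `spotdecode.pipeline` | Restartable decode→QC orchestration over fields of view |
| `spotdecode.cli` | `spotdecode` command-line entry point |

## CLI

```bash
# synthesize a field of view (codebook + spots + ground truth)
spotdecode simulate --config sim.yaml --out-prefix run1 --n-blanks 4

# decode
spotdecode decode --spots run1.spots.csv --codebook run1.codebook.json \
    --radius 1.5 --mode medium --error-rounds 0 --out transcripts.csv

# QC report (YAML)
spotdecode qc --transcripts transcripts.csv --spots run1.spots.csv \
    --codebook run1.codebook.json --out qc.yml

# elbow threshold + normalized AUC of a spot-count curve
spotdecode threshold --curve curve.csv --out report.json

# full multi-FOV pipeline from a config file; stages are restartable
spotdecode run --config run.yaml --stages decode,qc
```

`sim.yaml` holds `SimulationConfig` fields (`n_transcripts`, `fov_width`,
`fov_height`, `seed`, optional `drift_sigma`, `dropout_rate`,
`noise_spot_rate`, clustering). `run.yaml` lists the codebook, per-FOV spot
tables, an output directory, a seed, and the decode settings; see
`spotdecode.pipeline.RunConfig`.

## File formats

Everything is plain text: SpaceTx-style JSON codebooks (`{"mappings":
[{"codeword": [{"r": 0, "c": 2, "v": 1}, ...], "target": "gene"}]}`) or a TSV
dialect; spot tables as CSV with a `# fov_width=... fov_height=...` header
line; decoded transcripts as CSV with semicolon-joined source spot ids; QC
reports as YAML.
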