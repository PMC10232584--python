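# stresseeg

Analysis pipeline for two-condition (control vs. negative feedback)
EEG/ECG studies: relative spectral band power with 1/f correction,
orthogonalized amplitude-envelope-correlation (AEC) functional
connectivity between cortical regions of interest, event-related
inter-beat-interval (IBI) responses, and a mixed-model statistical layer
with AIC family selection, BIC-approximated Bayes factors and
Benjamini–Hochberg FDR correction — exercised end-to-end on synthetic
recordings with known ground truth.

## Modules

| Module | Role |
| --- | --- |
| `stresseeg.synthetic` | Ground-truth-known generator: band-limited oscillations with log-normal envelopes, controllable envelope coupling, linear channel mixing (leakage), R-peak trains with condition-dependent heart-rate acceleration, gamma-distributed scores. |
| `stresseeg.preprocess` | Threshold-based artifact detection (gradient / min–max / low activity), trigger-locked epoching, average re-reference, zero-phase band filtering. |
| `stresseeg.spectral` | Welch PSD, `f**exponent` 1/f correction, relative band power, frontal electrode averaging. |
| `stresseeg.connectivity` | ROI catalog (scout lists, PCA scout combination), pairwise Gram–Schmidt orthogonalization, Hilbert envelopes, two-way-averaged AEC, connection-space enumeration. |
| `stresseeg.cardiac` | Event-locked IBI extraction (indices −3…+8), re-referencing to IBI₋₂, condition contrast tables. |
| `stresseeg.stats` | Linear mixed model and gamma GLMM (identity link, Gauss–Hermite ML) with AIC selection, sex covariate check, BF01 from BIC, BH-FDR, test-family enumeration, inclusion rule. |
| `stresseeg.pipeline` | YAML configuration, end-to-end orchestration, CSV outputs and a markdown report. |

## CLI

```bash
# full synthetic study end-to-end (67-test family, report.md + CSVs)
stresseeg run --seed 1 --out out/

# individual stages
stresseeg simulate --seed 1 --out sim/ --participants 5
stresseeg preprocess recording.tsv --fs 512 --triggers triggers.csv --out epochs.txt
stresseeg power sim/P000_control_epochs.txt --out power.csv
stresseeg connectivity sim/P000_control_epochs.txt --out fc.csv
stresseeg cardiac --rpeaks sim/rpeaks.csv --events sim/events.csv --out ibi.csv
stresseeg stats power.csv --value-col relative_power --out stats.csv
stresseeg report stats.csv
```

A YAML run configuration can override every simulation and analysis
parameter (`stresseeg run --config cfg.yaml`); effect keys use
`region|band` and `regionA,regionB|band` syntax. Defaults are
demo-scale (10 participants at 256 Hz); study scale is 73 participants,
6.2-s epochs at 512 Hz.

## Notes

- Epoch data are exchanged as plain delimited text plus a JSON sidecar
  (`stresseeg.epochs.write_epochs_txt`); EDF input is not supported in
  this environment (no EDF reader available offline).
- ICA component removal, bad-channel interpolation and source
  reconstruction (head models, inverse solutions) are out of scope; the
  pipeline consumes cleaned channel- or ROI-level series, and spatial
  leakage is emulated by the synthetic mixing matrix.
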