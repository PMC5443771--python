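# Calibrated per-condition component models for the synthetic SEP generator.
#
# Each condition specifies the dominant (high-energy) component's latency,
# frequency and power moments, plus a list of smaller-component regions with
# their latency/frequency moments, per-subject occurrence probability and
# relative-energy band ("middle": 2-10% of signal energy, "low": 0.2-1%).
# The high-component moments and the injury-group region moments/rates come
# from the reported cohort statistics; regions without published statistics
# (all normal/sham small components, C5 low-energy, the C4 low-energy
# occurrence rate) are package choices documented in docs/methods.md.
#
# noise_sd is the per-sweep broadband noise SD in µV; each recording averages
# n_sweeps stimulus-locked sweeps, so the averaged-trace noise floor is
# noise_sd / sqrt(n_sweeps).

normal: &normal
  high:
    time_ms: {mean: 12.9, sd: 4.2}
    frequency_hz: {mean: 50.7, sd: 8.2}
    power_uv2: {mean: 50.4, sd: 28.5}
  regions:
    - {time_ms: {mean: 35.0, sd: 5.0}, frequency_hz: {mean: 25.0, sd: 10.0}, occurrence: 0.6, band: middle}
    - {time_ms: {mean: 8.0, sd: 2.0}, frequency_hz: {mean: 90.0, sd: 15.0}, occurrence: 0.4, band: middle}
    - {time_ms: {mean: 25.0, sd: 4.0}, frequency_hz: {mean: 60.0, sd: 20.0}, occurrence: 0.5, band: low}
    - {time_ms: {mean: 42.0, sd: 6.0}, frequency_hz: {mean: 95.0, sd: 15.0}, occurrence: 0.4, band: low}
  noise_sd: 0.1
  n_sweeps: 200

# surgical controls are statistically indistinguishable from normal
sham: *normal

C4:
  high: &injured_high
    time_ms: {mean: 15.1, sd: 6.7}
    frequency_hz: {mean: 34.7, sd: 12.3}
    power_uv2: {mean: 28.5, sd: 14.2}
  regions:
    # middle-energy regions (pooled C4/C6 statistics)
    - {time_ms: {mean: 13.1, sd: 3.8}, frequency_hz: {mean: 158.7, sd: 23.4}, occurrence: 0.583, band: middle}
    - {time_ms: {mean: 10.9, sd: 2.6}, frequency_hz: {mean: 78.1, sd: 12.0}, occurrence: 0.333, band: middle}
    - {time_ms: {mean: 37.2, sd: 6.7}, frequency_hz: {mean: 33.5, sd: 22.3}, occurrence: 0.5, band: middle}
    # single low-energy region; occurrence is a package choice (7/12)
    - {time_ms: {mean: 25.7, sd: 2.6}, frequency_hz: {mean: 66.4, sd: 20.8}, occurrence: 0.583, band: low}
  noise_sd: 0.1
  n_sweeps: 200

C5:
  high: *injured_high
  regions:
    - {time_ms: {mean: 16.9, sd: 4.7}, frequency_hz: {mean: 105.3, sd: 10.8}, occurrence: 0.583, band: middle}
    - {time_ms: {mean: 37.9, sd: 2.9}, frequency_hz: {mean: 65.6, sd: 24.5}, occurrence: 0.417, band: middle}
    # low-energy components of the C5 group are not tabulated; intermediate
    # placements, package choice
    - {time_ms: {mean: 25.0, sd: 5.0}, frequency_hz: {mean: 70.0, sd: 20.0}, occurrence: 0.4, band: low}
    - {time_ms: {mean: 40.0, sd: 7.0}, frequency_hz: {mean: 55.0, sd: 20.0}, occurrence: 0.4, band: low}
  noise_sd: 0.1
  n_sweeps: 200

C6:
  high: *injured_high
  regions:
    # middle-energy regions shared with C4 (pooled statistics)
    - {time_ms: {mean: 13.1, sd: 3.8}, frequency_hz: {mean: 158.7, sd: 23.4}, occurrence: 0.583, band: middle}
    - {time_ms: {mean: 10.9, sd: 2.6}, frequency_hz: {mean: 78.1, sd: 12.0}, occurrence: 0.333, band: middle}
    - {time_ms: {mean: 37.2, sd: 6.7}, frequency_hz: {mean: 33.5, sd: 22.3}, occurrence: 0.5, band: middle}
    # two low-energy regions
    - {time_ms: {mean: 18.5, sd: 3.8}, frequency_hz: {mean: 100.0, sd: 12.2}, occurrence: 0.5, band: low}
    - {time_ms: {mean: 41.3, sd: 7.6}, frequency_hz: {mean: 53.9, sd: 21.9}, occurrence: 0.5, band: low}
  noise_sd: 0.1
  n_sweeps: 200
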