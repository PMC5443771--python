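# Canonical important distribution regions of the small SEP components,
# per group and energy category: rectangle bounds, reported local PDF peak,
# and the cohort the occurrence denominators refer to. Used by the region
# summarization step as the reference rectangles.

middle:
  C4C6:  # pooled C4 + C6 cohort (n = 24)
    - {name: region1, time_ms: [0, 25], freq_hz: [125, 225], peak: [13.1, 153.0]}
    - {name: region2, time_ms: [0, 25], freq_hz: [50, 125], peak: [11.7, 79.5]}
    - {name: region3, time_ms: [25, 50], freq_hz: [0, 75], peak: [36.2, 13.0]}
  C5:
    - {name: region1, time_ms: [10, 25], freq_hz: [75, 125], peak: [21.5, 100.5]}
    - {name: region2, time_ms: [30, 45], freq_hz: [25, 100], peak: [35.5, 83.0]}

low:
  C4:
    - {name: region1, time_ms: [20, 30], freq_hz: [0, 100], peak: [27.8, 55.0]}
  C6:
    - {name: region1, time_ms: [5, 25], freq_hz: [75, 125], peak: [18.7, 100.5]}
    - {name: region2, time_ms: [30, 50], freq_hz: [0, 100], peak: [30.6, 83.0]}
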