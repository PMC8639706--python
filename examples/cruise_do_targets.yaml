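# Template configuration: the cruise's fixed DO sampling targets
# (200, 100, 50, 20, 10, 5 and 1 uM), expressed in nM as the initial
# DO levels of an oxygen-manipulation experiment on OMZ-edge water.
# Run with:  omzox all --config examples/cruise_do_targets.yaml --out results/cruise
seed: 1
scenario: omz_edge
DO_levels: [200000, 100000, 50000, 20000, 10000, 5000, 1000]
duration_hours: 24.0
sensor_detection_limit: 100.0  # wide-range sensor spots
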