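# Template configuration: a secondary-chlorophyll-maximum oxygen
# manipulation — eight initial DO levels from tens of nM to tens of uM,
# trace-level sensor spots (10 nM detection limit), 24 bottles total.
# Run with:  omzox all --config examples/scm_experiment.yaml --out results/scm
seed: 1
scenario: scm
DO_levels: [30, 60, 120, 250, 500, 1000, 4000, 16000]
duration_hours: 24.0
sensor_sd: 2.0
sensor_detection_limit: 10.0
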