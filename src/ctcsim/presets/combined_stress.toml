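# Combined threat x resource grid for high-density clusters of 20 and
# 100 cells (threat and resource deprivation applied together).
[design]
density_classes = ["high"]
sizes = [20, 100]
threat_levels = [0.05, 0.4, 0.5]
resource_levels = [0.2, 0.4, 0.8]
n_replicates = 200
base_seed = 0
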