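# Threat intensity sweep at very high resource levels.
[design]
density_classes = ["high", "medium", "low"]
sizes = [40, 80, 100]
threat_levels = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
resource_levels = [1.0]
n_replicates = 200
base_seed = 0
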