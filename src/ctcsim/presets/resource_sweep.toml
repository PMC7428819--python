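# Resource availability sweep (very low .. very high) at very low threat.
[design]
density_classes = ["high", "medium", "low"]
sizes = [20, 40, 80, 100]
threat_levels = [0.05]
resource_levels = [0.2, 0.4, 0.6, 0.8, 1.0]
n_replicates = 200
base_seed = 0
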