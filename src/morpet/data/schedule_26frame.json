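[[0, 15], [15, 15], [30, 15], [45, 15], [60, 15], [75, 15], [90, 15], [105, 15], [120, 60], [180, 60], [240, 60], [300, 120], [420, 120], [540, 120], [660, 120], [780, 120], [900, 300], [1200, 300], [1500, 300], [1800, 300], [2100, 300], [2400, 600], [3000, 600], [3600, 600], [4200, 600], [4800, 600]]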