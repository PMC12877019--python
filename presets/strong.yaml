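# immunotile synthetic-cohort preset (v1)
# Load with immunotile.synthetic.load_preset("presets/strong.yaml").
# Fields not listed here keep the generator defaults (4 responders /
# 8 non-responders, 3 mm x 3 mm slides, lymphoid marker panel).
effect_preset: strong
seed: 0
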