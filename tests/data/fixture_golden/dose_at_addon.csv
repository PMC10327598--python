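patient_id,levodopa_dose_at_addon_mg
P02,300.0
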