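from hypothesis import settings

# deterministic property tests, no per-run example database
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
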