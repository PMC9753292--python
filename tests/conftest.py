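from hypothesis import HealthCheck, settings

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=50,
    suppress_health_check=list(HealthCheck),
    deadline=None,
)
settings.load_profile("fast")
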