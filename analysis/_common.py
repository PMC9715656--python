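"""Shared driver setup: the reference scene and result directories."""

from pathlib import Path

from vegwater import GeneratorConfig, PipelineConfig, run_all

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def reference_run():
    """Full pipeline on the reference scene (64 x 64 pixels, water years
    2001-2019, seed 1)."""
    cfg = PipelineConfig(generator=GeneratorConfig(seed=SEED))
    return run_all(cfg)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
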