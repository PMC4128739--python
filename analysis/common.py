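"""Shared paths and run parameters for the numbered analysis scripts.

Each script writes its outputs under results/ and later scripts read them
back through the package's file formats, so every stage is independently
re-runnable. The root seed fixes the whole analysis.
"""

from pathlib import Path

from patchlink.pipeline import default_config

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 2011

PLOTS = ("natural", "managed")


def config():
    return default_config(seed=SEED)


def require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise SystemExit(f"missing {path}; run {producer} first")
    return path
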