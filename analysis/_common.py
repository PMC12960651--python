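"""Shared plumbing for the analysis drivers."""

import sys
from pathlib import Path

_SRC = Path(__file__).resolve().parents[1] / "src"
if str(_SRC) not in sys.path:
    sys.path.insert(0, str(_SRC))

add_src_to_path = True  # importing this module is enough

RESULTS = Path(__file__).resolve().parents[1] / "results"


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
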