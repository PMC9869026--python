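"""Shared plumbing for the numbered analysis scripts.

The scripts operate on one deterministic synthetic community fixture
(seed 42, mean per-replicon depth 6x) kept under scratch/ — large
simulated files never live in the repository; tables land under results/.
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
FIXTURE = SCRATCH / "fixture_seed42"
SEED = 42
DEPTH = 6.0


def ensure_fixture():
    """Generate the shared community fixture if it is not on disk yet."""
    from hifimag.synthio import write_fixture

    RESULTS.mkdir(exist_ok=True)
    if not (FIXTURE / "reads.fastq").exists():
        print(f"generating fixture (seed {SEED}, depth {DEPTH}x) ...")
        write_fixture(FIXTURE, seed=SEED, depth_target=DEPTH)
    return FIXTURE
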