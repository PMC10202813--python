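"""Shared plumbing for the numbered analysis drivers.

The cohort lives under scratch/cohort (regenerated deterministically when
absent); summary tables land in results/.
"""

from pathlib import Path

from ramscape.io import load_cohort, read_truth, write_cohort, write_truth
from ramscape.simulate import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 11


def get_cohort():
    """Load the study cohort, simulating and caching it on first use."""
    RESULTS.mkdir(exist_ok=True)
    truth_path = SCRATCH / "truth.json"
    if truth_path.exists():
        return load_cohort(SCRATCH), read_truth(truth_path)
    config = SimulationConfig(seed=SEED)
    bundle, truth = simulate_cohort(config)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    write_cohort(bundle, SCRATCH)
    write_truth(truth, truth_path)
    return bundle, truth
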