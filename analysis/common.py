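"""Shared paths and loaders for the numbered analysis scripts.

The synthetic cohort (the study's input data) is regenerated under scratch/
because it is bulky; the small result tables land under results/analysis/.
Every script can be re-run independently as long as 01 ran first.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
COHORT_DIR = ROOT / "scratch" / "cohort"
RESULTS_DIR = ROOT / "results" / "analysis"
SEED = 20260926 % 2**31


def cohort_paths() -> dict[str, Path]:
    names = {
        "cnv": "cnv_calls.tsv", "mrna": "expr_mrna.tsv",
        "lncrna": "expr_lncrna.tsv", "mirna": "expr_mirna.tsv",
        "interactions": "interactions.tsv", "clinical": "clinical.tsv",
        "truth": "truth.json",
    }
    return {k: COHORT_DIR / v for k, v in names.items()}


def require_cohort() -> dict[str, Path]:
    paths = cohort_paths()
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise SystemExit(
            "cohort inputs missing; run analysis/01_simulate_cohort.py first "
            f"(missing: {missing[0]} ...)")
    return paths
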