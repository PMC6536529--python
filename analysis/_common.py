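"""Shared paths and grid loading for the numbered analysis scripts."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"
GRID_DIR = RESULTS / "grids"


def load_grids(variant: str):
    """Load the kerma grids written by 02_transport_grids.py."""
    from isomap.gridio import read_grid
    paths = sorted(GRID_DIR.glob(f"{variant}_p*.csv"))
    if not paths:
        raise SystemExit(
            f"no grids found under {GRID_DIR} - run analysis/02_transport_grids.py first")
    return [read_grid(p) for p in paths]
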