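import numpy as np
import pytest

import skimcnv as sc


@pytest.fixture(scope="session")
def small_grid():
    """Two small chromosomes, 10 kb windows, flat mappability."""
    return sc.make_genome({"chrA": 2_000_000, "chrB": 1_000_000}, seed=0)


@pytest.fixture(scope="session")
def small_population():
    """A 10-line population on a 30 Mb genome with implanted events.

    Session-scoped because several test modules only read from it.
    """
    grid = sc.make_genome(
        {"chr1": 15_000_000, "chr2": 15_000_000}, mappability_sd=0.1, seed=7
    )
    truth = sc.implant_events(
        grid,
        n_lines=10,
        events_per_line=2,
        min_size=50_000,
        max_size=1_000_000,
        zygosity_mix={"hom_del": 0.5, "hemi_del": 0.35, "dup": 0.15},
        seed=7,
    )
    config = sc.SimConfig(n_lines=10, mean_reads_per_window=67.0, marker_count=3_000, seed=7)
    raw = sc.simulate_depth(grid, truth, config)
    norm = sc.normalize(raw)
    stats = sc.window_stats(norm)
    return {
        "grid": grid,
        "truth": truth,
        "config": config,
        "raw": raw,
        "norm": norm,
        "stats": stats,
    }


def brute_force_runs(flags, gap_tolerance):
    """Independent reference for run assembly.

    Renders the track as a 0/1 string and lets the regex engine find
    maximal groups greedily: a run is ``1`` optionally extended by
    blocks of at most ``gap_tolerance`` zeros followed by another ``1``.
    A completely different mechanism from the array arithmetic it
    checks.
    """
    import re

    s = "".join("1" if f else "0" for f in flags)
    pattern = re.compile(r"1(?:0{0,%d}1)*" % gap_tolerance)
    out = []
    for m in pattern.finditer(s):
        body = m.group(0)
        out.append(
            {
                "first": m.start(),
                "last": m.end() - 1,
                "n_flagged": body.count("1"),
                "n_interruptions": body.count("0"),
            }
        )
    return out
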