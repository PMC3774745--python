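import numpy as np
import pytest

from cnaloh.genome import GenomeMap, default_genome
from cnaloh.loh import call_genotypes, detect_loh
from cnaloh.merge import merge_loh_cn
from cnaloh.segmentation import call_states, paired_log_ratio, segment
from cnaloh.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_genome() -> GenomeMap:
    """Three 3-Mb chromosomes (including chr 5), one marker per 5 kb."""
    pos = np.arange(5_000, 3_000_001, 5_000, dtype=np.int64)
    return GenomeMap(
        chromosomes=("1", "2", "5"),
        lengths={c: 3_000_000 for c in ("1", "2", "5")},
        positions={c: pos.copy() for c in ("1", "2", "5")},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort at its configured seed (full scale)."""
    config = CohortConfig()
    genome = default_genome()
    return simulate_cohort(config, genome, seed=config.seed)


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    """Full pipeline calls (segments, LOH, classified LOH) on the default cohort."""
    genome = default_cohort.genome
    segments, loh, classified = {}, {}, {}
    for sid, prof in default_cohort.profiles.items():
        segs = segment(paired_log_ratio(prof), genome, sample_id=sid)
        segs = call_states(segs)
        segments[sid] = segs
        t_gt = call_genotypes(prof.tumor_baf, prof.tumor_mask)
        n_gt = call_genotypes(prof.normal_baf, prof.normal_mask)
        loh[sid] = detect_loh(t_gt, n_gt, genome, sample_id=sid)
        classified[sid] = merge_loh_cn(loh[sid], segs, genome)
    return {"segments": segments, "loh": loh, "classified": classified}
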