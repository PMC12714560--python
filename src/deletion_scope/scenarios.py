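"""Canonical simulation scenarios mirroring the sequenced study conditions.

The pooled-colony scenario plants, on a 200 kb genome carrying four
identical IS elements (768 bp, 30 bp terminal inverted repeats):

* a 13,100 bp deletion bounded at an IS terminal repeat (pool fraction 0.4),
* a 43,800 bp deletion bounded at the SAME repeat boundary (fraction 0.3),
  so the two deletions nest the way the study's deletions shared one
  conserved IS1 IRR boundary upstream of the target gene, and
* a 150 bp deletion with 6 bp of planted microhomology, the alternative
  end-joining signature (fraction 0.3),

then draws pooled 100 bp single-end reads at 30x mean depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from deletion_scope.model import DeletionEvent, GenomeModel, Lineage, SimulationParams
from deletion_scope.synthetic import PoolResult, build_genome, plant_deletion, simulate_pool


@dataclass
class PooledScenario:
    genome: GenomeModel
    lineages: list[Lineage]
    params: SimulationParams
    pool: PoolResult
    events: dict[str, DeletionEvent]
    coverage_region: tuple[int, int]
    exclusion: tuple[int, int]

    @property
    def truth(self) -> pd.DataFrame:
        return self.pool.truth


def pooled_deletion_scenario(
    seed: int = 1,
    genome_length: int = 200_000,
    n_is: int = 4,
    depth: float = 30.0,
    read_length: int = 100,
    large_sizes: tuple[int, int] = (13_100, 43_800),
    small_size: int = 150,
    mh_len: int = 6,
    fractions: tuple[float, float, float] = (0.4, 0.3, 0.3),
    mapq_low_fraction: float = 0.0,
) -> PooledScenario:
    """Build the pooled three-lineage deletion scenario.

    Both large deletions are anchored at one IS element's terminal-repeat
    boundary chosen so the larger fits inside the genome, making them
    nested; the combined dropout inside the nested interval is what a
    fractional-of-median coverage threshold can detect in a pool.
    """
    genome = build_genome(
        length=genome_length,
        gc=0.5,
        n_is=n_is,
        is_length=768,
        ir_length=30,
        gene_spec=[("lacZ", 3075), ("lacI", 1083)],
        seed=seed,
    )
    bigger = max(large_sizes)
    # anchor both large deletions at the same repeat boundary of one element
    anchor = None
    for elem in genome.is_elements:
        if elem.irr[1] - bigger >= 0:
            anchor = (elem.id, "IRR")
            break
    if anchor is None:
        for elem in genome.is_elements:
            if elem.irl[0] + bigger <= len(genome):
                anchor = (elem.id, "IRL")
                break
    if anchor is None:
        raise RuntimeError("no IS element admits the largest deletion")

    _, ev_small = plant_deletion(
        genome, "AEJ", size=small_size, mh_len=mh_len, seed=seed + 101
    )
    _, ev_large1 = plant_deletion(genome, "IS_BOUNDED", size=large_sizes[0], anchor=anchor)
    _, ev_large2 = plant_deletion(genome, "IS_BOUNDED", size=large_sizes[1], anchor=anchor)

    lineages = [
        Lineage(id="linA", deletions=(ev_large1,), pool_fraction=fractions[0]),
        Lineage(id="linB", deletions=(ev_large2,), pool_fraction=fractions[1]),
        Lineage(id="linC", deletions=(ev_small,), pool_fraction=fractions[2]),
    ]
    params = SimulationParams(
        depth=depth,
        read_length=read_length,
        min_anchor=10,
        seed=seed,
        mapq_low_fraction=mapq_low_fraction,
    )
    pool = simulate_pool(genome, lineages, params)

    lo = min(ev_large1.left_break, ev_large2.left_break)
    hi = max(ev_large1.right_break, ev_large2.right_break)
    # flanks must outweigh the deleted span so the region median reflects
    # full pool depth rather than the partial dropout
    margin = 25_000
    region = (max(0, lo - margin), min(len(genome), hi + margin))
    # plasmid-borne-gene-style exclusion window inside the left flank
    excl_start = region[0] + 1_000
    exclusion = (excl_start, excl_start + 1_083)

    return PooledScenario(
        genome=genome,
        lineages=lineages,
        params=params,
        pool=pool,
        events={"large_nested": ev_large1, "large_outer": ev_large2, "small_aej": ev_small},
        coverage_region=region,
        exclusion=exclusion,
    )
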