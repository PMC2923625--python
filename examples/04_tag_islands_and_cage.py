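"""Call ChIP tag islands and classify promoter pairs by mark and CAGE status.

Generates a synthetic bundle with tags planted at active promoters, calls
islands with the 3-tags-per-100-bp rule, assigns YES/NONE status per
promoter, and reports median inter-TSS distance per joint category plus the
CAGE-supported fraction.
"""

from promoterome import (
    cage_support,
    call_dalfe_pairs,
    call_tag_islands,
    cluster_isoforms,
    distance_by_status,
    promoter_status,
)
from promoterome.simulate import SimConfig, generate

cfg = SimConfig(seed=4, n_genes=120)
result = generate(cfg)
genes = cluster_isoforms(result.transcripts, result.cluster_map)
kept, _, _ = call_dalfe_pairs(
    genes, repeats=result.repeats, probes=[p.exon for p in result.probes]
)

islands = call_tag_islands(result.tags[cfg.chrom], chrom=cfg.chrom)
print(f"{len(islands)} tag islands called from {len(result.tags[cfg.chrom])} tags")

evidences = [promoter_status(p, islands) for p in kept]
medians = distance_by_status(kept, evidences)
print("median inter-TSS distance by joint P1|P2 mark status:")
for joint, med in medians.items():
    print(f"  {joint:10s} {'-' if med is None else f'{med:,.0f} bp'}")

_, frac = cage_support(kept, result.cage_clusters)
print(f"\nCAGE-supported promoters: {frac:.0%}")
# Co-marked pairs sit closer together than discordant ones, and most TSSs
# are corroborated by a strand-matched CAGE tag cluster.
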