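"""Brute-force reference for the combination engine.

Each printed combination line is translated literally into a boolean test
over the per-category counts (PVS, PS, PM, PP, BA, BS, BP), independent of
the engine's data-driven predicate machinery.  Thresholds are lower bounds
for the same reason the engine's are: extra evidence is never exculpatory.
"""


def oracle_tier(counts, dialect="paper_verbatim"):
    """Return (tier_name, via_contradiction) for one count vector."""
    PVS, PS, PM, PP, BA, BS, BP = counts

    pathogenic = (
        (PVS >= 1 and PS >= 1)
        or (PVS >= 1 and PM >= 2)
        or (PVS >= 1 and PS >= 1 and PM >= 1)
        or (PVS >= 1 and PP >= 2)
        or (PS >= 2)
        or (PS >= 1 and PM >= 3)
        or (PS >= 1 and PM >= 2 and PP >= 2)
        or (PS >= 1 and PM >= 1 and PP >= 4)
    )
    if dialect == "acmg2015":
        pathogenic = pathogenic or (PVS >= 1 and PM >= 1 and PP >= 1)

    likely_pathogenic = (
        (PVS >= 1 and PM >= 1)
        or (PS >= 1 and PM >= 1)
        or (PS >= 1 and PP >= 2)
        or (PM >= 2 and PP >= 2)
        or (PM >= 1 and PP >= 4)
    )
    if dialect == "acmg2015":
        likely_pathogenic = likely_pathogenic or PM >= 3
    else:
        likely_pathogenic = likely_pathogenic or PP >= 3

    benign = BA >= 1 or BS >= 2
    likely_benign = (BS >= 1 and BP >= 1) or BP >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return "uncertain_significance", True
    if pathogenic:
        return "pathogenic", False
    if likely_pathogenic:
        return "likely_pathogenic", False
    if benign:
        return "benign", False
    if likely_benign:
        return "likely_benign", False
    return "uncertain_significance", False
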