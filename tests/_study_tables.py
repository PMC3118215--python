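"""Published summary counts from the mouse MeDIP-chip developmental
methylation survey (4 tissues x 3 stages, promoter + CpG-island array),
entered as inputs for table-arithmetic checks.

Per-pattern rows carry (total, CpGi-promoter, non-CpGi-promoter,
intragenic-CpGi, intergenic-CpGi) counts.
"""

from dmrscan import LocationCategory

CATS = (
    LocationCategory.CPGI_PROMOTER,
    LocationCategory.NONCPGI_PROMOTER,
    LocationCategory.INTRAGENIC_CPGI,
    LocationCategory.INTERGENIC_CPGI,
)

# Adult T-DMR table: pattern -> (total, cpgi_prom, noncpgi_prom, intra, inter)
TDMR_TABLE = {
    ("brain", "heart", "liver", "testis"): (460, 18, 230, 163, 49),  # Common
    ("brain",): (285, 68, 173, 23, 21),
    ("heart",): (822, 223, 428, 115, 56),
    ("liver",): (711, 155, 428, 66, 62),
    ("testis",): (1294, 44, 1215, 20, 15),
    ("brain", "heart"): (482, 69, 282, 89, 42),
    ("brain", "liver"): (12, 2, 7, 2, 1),
    ("brain", "testis"): (26, 1, 25, 0, 0),
    ("heart", "liver"): (49, 7, 24, 13, 5),
    ("heart", "testis"): (47, 0, 45, 2, 0),
    ("liver", "testis"): (305, 3, 268, 27, 7),
    ("brain", "heart", "liver"): (414, 65, 148, 127, 74),
    ("brain", "heart", "testis"): (175, 3, 151, 19, 2),
    ("brain", "liver", "testis"): (18, 0, 15, 2, 1),
    ("heart", "liver", "testis"): (46, 4, 37, 4, 1),
}
TDMR_TOTALS = {
    "unique": 3112,
    "multi": 1574,
    "all": 4686,
    "common": 460,
    "category_all": (644, 3246, 509, 287),
    "category_pct": (13.7, 69.3, 10.9, 6.1),
}

# Stage-specific table, per tissue: pattern -> (total, cpgi, noncpgi, intra, inter)
DSDMR_TABLES = {
    "brain": {
        ("E15", "NB", "AD"): (1903, 182, 1018, 493, 210),
        ("E15",): (533, 105, 359, 35, 34),
        ("E15", "NB"): (490, 66, 368, 29, 27),
        ("NB",): (370, 55, 248, 42, 25),
        ("AD",): (408, 94, 233, 52, 29),
        ("NB", "AD"): (70, 5, 40, 16, 9),
        ("E15", "AD"): (65, 11, 46, 7, 1),
    },
    "heart": {
        ("E15", "NB", "AD"): (1844, 218, 946, 491, 189),
        ("E15",): (46, 27, 8, 2, 9),
        ("E15", "NB"): (87, 17, 61, 4, 5),
        ("NB",): (93, 12, 64, 7, 10),
        ("AD",): (172, 45, 83, 33, 11),
        ("NB", "AD"): (246, 44, 132, 54, 16),
        ("E15", "AD"): (27, 6, 15, 5, 1),
    },
    "liver": {
        ("E15", "NB", "AD"): (1497, 141, 726, 425, 205),
        ("E15",): (117, 25, 74, 10, 8),
        ("E15", "NB"): (1419, 198, 1034, 125, 62),
        ("NB",): (147, 24, 109, 8, 6),
        ("AD",): (468, 70, 322, 45, 31),
        ("NB", "AD"): (36, 2, 30, 3, 1),
        ("E15", "AD"): (194, 13, 130, 31, 20),
    },
    "testis": {
        ("E15", "NB", "AD"): (570, 20, 363, 148, 39),
        ("E15",): (272, 105, 101, 33, 33),
        ("E15", "NB"): (939, 193, 480, 157, 109),
        ("NB",): (798, 231, 391, 86, 90),
        ("AD",): (2214, 71, 1908, 165, 70),
        ("NB", "AD"): (63, 3, 48, 9, 3),
        ("E15", "AD"): (62, 5, 38, 14, 5),
    },
}
DSDMR_PER_TISSUE_TOTALS = {
    "brain": {"all": 1936, "UnMe-AD": 1393, "Me-AD": 543, "common": 1903},
    "heart": {"all": 671, "UnMe-AD": 226, "Me-AD": 445, "common": 1844},
    "liver": {"all": 2381, "UnMe-AD": 1683, "Me-AD": 698, "common": 1497},
    "testis": {"all": 4348, "UnMe-AD": 2009, "Me-AD": 2339, "common": 570},
}
DSDMR_GRAND_TOTALS = {
    "all": 9336,
    "UnMe-AD": 5311,
    "Me-AD": 4025,
    "common": 5814,
    "category_all": (1427, 6322, 972, 615),
    "category_pct": (15.3, 67.7, 10.4, 6.6),
}

# Cross-tissue overlap of stage-specific DMRs:
# tissue -> (all, tissue-unique, in-multiple-tissues)
CROSS_TISSUE = {
    "brain": (1973, 1065, 908),
    "heart": (867, 533, 334),
    "liver": (3570, 2160, 1410),
    "testis": (5469, 4099, 1370),
}
CROSS_TOTALS = {
    "total_with_multiplicity": 11879,
    "multi_with_multiplicity": 4022,
    "n_unique": 7857,
    "n_multi_clusters": 1927,
    "dedup_total": 9784,
    "unique_pct": 80.3,
}


def tdmr_count_spec():
    """Table counts as a fixture_from_counts spec (per pattern, per category)."""
    return {
        pattern: dict(zip(CATS, row[1:]))
        for pattern, row in TDMR_TABLE.items()
    }


def dsdmr_count_spec(tissue):
    return {
        pattern: dict(zip(CATS, row[1:]))
        for pattern, row in DSDMR_TABLES[tissue].items()
    }


def cross_tissue_interval_sets():
    """Construct per-tissue interval sets realizing the overlap accounting.

    Unique regions are placed disjointly per tissue. Shared regions are built
    as overlap clusters whose sizes follow from the totals: with only 2- and
    3-tissue clusters, n3 = members - 2*clusters and n2 = clusters - n3.
    Cluster tissue membership is assigned greedily (largest remaining
    counts first), which succeeds whenever no tissue holds more than half
    the pair memberships.
    """
    from dmrscan import GenomicInterval

    tissues = list(CROSS_TISSUE)
    remaining = {t: CROSS_TISSUE[t][2] for t in tissues}
    members = sum(remaining.values())
    n_clusters = CROSS_TOTALS["n_multi_clusters"]
    n3 = members - 2 * n_clusters
    n2 = n_clusters - n3
    assert n3 >= 0 and n2 >= 0

    sets = {t: [] for t in tissues}
    pos = 0
    for t, (_, uniq, _) in CROSS_TISSUE.items():
        for _ in range(uniq):
            sets[t].append(GenomicInterval("chrX", pos, pos + 500))
            pos += 1000

    def take(k):
        nonlocal pos
        chosen = sorted(remaining, key=lambda t: (-remaining[t], t))[:k]
        for t in chosen:
            assert remaining[t] > 0
            remaining[t] -= 1
            sets[t].append(GenomicInterval("chrX", pos, pos + 500))
        pos += 1000

    for _ in range(n3):
        take(3)
    for _ in range(n2):
        take(2)
    assert all(v == 0 for v in remaining.values())
    return sets
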