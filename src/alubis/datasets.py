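"""Bundled example data: the published per-library counts and verified
insertion features from an eight-library Alu-anchored bisulfite PCR study
of human cerebellum and ependymoma samples.

These tables serve as worked-example inputs for the reporting code: the
cluster-table reconstruction in :func:`build_example_clusters` lays out a
synthetic cluster configuration whose per-library marginals equal the
published counts, so that :func:`alubis.calling.summarize_libraries`
recomputes every summary statistic from first principles.
"""

from __future__ import annotations

import pandas as pd

from alubis.calling import InsertionCluster

LIBRARIES = ("NC1", "NC2", "PA1", "PA2", "PA3", "PA4", "PA5", "RL")

TISSUE_CLASSES = {
    "NC1": "normal", "NC2": "normal",
    "PA1": "tumor", "PA2": "tumor", "PA3": "tumor",
    "PA4": "tumor", "PA5": "tumor", "RL": "tumor",
}

#: Per-library totals: mapped reads/regions and candidate-insertion
#: reads/regions.
LIBRARY_COUNTS = {
    "NC1": dict(reads_mapped=245_825, regions_mapped=31_871,
                insertion_reads=56, insertion_regions=28),
    "NC2": dict(reads_mapped=460_438, regions_mapped=47_071,
                insertion_reads=692, insertion_regions=159),
    "PA1": dict(reads_mapped=256_014, regions_mapped=31_683,
                insertion_reads=78, insertion_regions=36),
    "PA2": dict(reads_mapped=238_633, regions_mapped=33_760,
                insertion_reads=216, insertion_regions=61),
    "PA3": dict(reads_mapped=336_103, regions_mapped=41_485,
                insertion_reads=453, insertion_regions=113),
    "PA4": dict(reads_mapped=283_730, regions_mapped=33_937,
                insertion_reads=203, insertion_regions=62),
    "PA5": dict(reads_mapped=276_505, regions_mapped=33_052,
                insertion_reads=23, insertion_regions=16),
    "RL": dict(reads_mapped=245_600, regions_mapped=36_957,
               insertion_reads=41, insertion_regions=23),
}

#: Cluster-level counts reported alongside the library table.
CLUSTER_COUNTS = dict(
    n_clusters=327,
    n_multi_read=163,
    n_multi_library=87,
    n_shared_normal_tumor=56,
    n_novel=316,
    n_intronic=140,
    validation_selected=21,
    validation_verified=19,
)

#: Verified insertion loci: subfamily, TSD, putative cleavage site, and the
#: raw poly-A tail-region string.
VERIFIED_INSERTIONS = (
    ("AI-1", "chr15:61216453-61216621", "AluY", "AAGAAATGTTCT", "TTAA",
     "CTCAAAAAAAAAAAAAAAGAAAAAAAAAAAAGAAAAAAGAAAT"),
    ("AI-2", "chr5:139595078-139595241", "AluYb8", "TAAATTACAGA", "TTAAA",
     "CTCAAAAAAAAAAAAAAAATAAATAAATAAATAAATTA"),
    ("AI-3", "chr4:41598260-41598327", "AluY", "AAGTACATGTGG", "TGGAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGAAGT"),
    ("AI-4", "chr13:23662855-23663027", "AluYa5", "CATCTG", "TTAAAA",
     "CTCCGTCTCAAAAAAAAAAAAAACAAAAAAAAAAACAAAAAAAAAAAACATCT"),
    ("AI-5", "chr15:28179309-28179438", "AluY", "ATAAAACATGGTCTG", "TATAAAA",
     "CTCAAAAAAAAAAAAAAAATAAAAAAAAATAAATAAAAAAATAAAACAT"),
    ("AI-6", "chr12:32076361-32076491", "AluYg6", "GAAATAATTGATCT", "TGAAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAGAAATAAT"),
    ("AI-7", "chr11:130675880-130675924", "AluY", "AAAAAGAAGC", "TTAAAA",
     "CTCAAAAAAAAAAAAAAAAAAAAGAAGCA"),
    ("AI-8", "chr5:141758572-141758694", "AluYb8", "AAAAATGGGGATT", "TTAAAA",
     "CTCAAAAAAAAAAAAAAAAAATGGGGA"),
    ("AI-9", "chr10:107891481-107891638", "AluYg6", "CGTGTGCTC", "TTAAAA",
     "CTCAAAAAAAAAAACGTGTG"),
    ("AI-10", "chr10:72605338-72605440", "AluYg6", "AAGAAGGTA", "TAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGAAGGT"),
    ("AI-11", "chr2:48276482-48276601", "AluYb8", "AGAAATTCAAATGCA", "TTA",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGAAAT"),
    ("AI-12", "chr5:16716576-16716677", "AluYg6", "AAGAAGTATGACAG", "TAA",
     "CTCAAAAAAAAAAAAAAAAAAAAGAAGTAT"),
    ("AI-13", "chr12:24518543-24518646", "AluY", "AAAAAAGTATTAATCA", "TTAAAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGTAT"),
    ("AI-14", "chr6:57403535-57403610", "AluY", "TCCTA", "TAAT",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAATTCC"),
    ("AI-15", "chr2:9888790-9888862", "AluYb8", "CACACCCGTG", "TAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAACACAC"),
    ("AI-16", "chr9:1631754-1631884", "AluYb8", "AAGAA", "CAAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAGAAAACA"),
    ("AI-17", "chr4:139225139-139225274", "AluY", "GAGTTTTTAAACATCT", "TTAAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAAGGAGT"),
    ("AI-18", "chr2:26623669-26623732", "AluYb8", "AAAATCAGTTCTTCC", "TTAAAA",
     "CTCAAAAAAAAAAAAAAAAAAAAAAAAAAAAAATCAGTT"),
    ("AI-19", "chr9:37594172-37594310", "AluY", "AAGAAGTAGATATGG", "TAA",
     "CTCCAAAAAAAAAAAAAAGAAG"),
)


def library_counts_frame() -> pd.DataFrame:
    return pd.DataFrame(
        [{"library_id": lib, **LIBRARY_COUNTS[lib]} for lib in LIBRARIES]
    )


def mapping_totals() -> dict[str, dict[str, int]]:
    return {
        lib: {
            "reads_mapped": LIBRARY_COUNTS[lib]["reads_mapped"],
            "regions_mapped": LIBRARY_COUNTS[lib]["regions_mapped"],
        }
        for lib in LIBRARIES
    }


def verified_polya_regions() -> dict[str, str]:
    return {row[0]: row[5] for row in VERIFIED_INSERTIONS}


def build_example_clusters() -> list[InsertionCluster]:
    """Deterministically reconstruct a cluster table matching the published
    marginals.

    The published table gives only marginal totals; this builds one
    concrete configuration consistent with all of them: 327 clusters, the
    per-library insertion-read and insertion-region counts, 163 clusters
    with more than one read, 87 clusters spanning more than one library,
    56 of those shared between normal and tumor libraries, and 316 novel
    clusters.  Every summary statistic must then be recomputed from the
    cluster table itself.
    """
    normals = [lib for lib in LIBRARIES if TISSUE_CLASSES[lib] == "normal"]
    tumors = [lib for lib in LIBRARIES if TISSUE_CLASSES[lib] == "tumor"]
    region_left = {lib: LIBRARY_COUNTS[lib]["insertion_regions"] for lib in LIBRARIES}

    n_clusters = CLUSTER_COUNTS["n_clusters"]
    n_multi_lib = CLUSTER_COUNTS["n_multi_library"]
    n_shared = CLUSTER_COUNTS["n_shared_normal_tumor"]
    total_regions = sum(region_left.values())

    members: list[list[str]] = []
    # mixed normal/tumor multi-library clusters
    for _ in range(n_shared):
        n_lib = max(normals, key=lambda l: region_left[l])
        t_lib = max(tumors, key=lambda l: region_left[l])
        region_left[n_lib] -= 1
        region_left[t_lib] -= 1
        members.append([n_lib, t_lib])
    # same-class (tumor-only) multi-library clusters
    for _ in range(n_multi_lib - n_shared):
        first, second = sorted(tumors, key=lambda l: -region_left[l])[:2]
        region_left[first] -= 1
        region_left[second] -= 1
        members.append([first, second])
    # distribute the remaining incidences beyond one-per-cluster-per-side
    extra_incidences = total_regions - n_clusters - n_multi_lib
    i = 0
    while extra_incidences > 0:
        cluster = members[i % n_multi_lib]
        is_mixed = i % n_multi_lib < n_shared
        pool = LIBRARIES if is_mixed else tumors
        candidates = [l for l in pool if l not in cluster and region_left[l] > 0]
        if candidates:
            lib = max(candidates, key=lambda l: region_left[l])
            region_left[lib] -= 1
            cluster.append(lib)
            extra_incidences -= 1
        i += 1
        if i > 100_000:
            raise RuntimeError("cluster reconstruction failed to converge")
    # singleton clusters consume what is left
    for lib in LIBRARIES:
        members.extend([lib] for _ in range(region_left[lib]))
    assert len(members) == n_clusters

    # read counts: one per incidence, then extras; exactly
    # (n_multi_read - n_multi_lib) singletons become multi-read
    counts = [{lib: 1 for lib in libs} for libs in members]
    extra_reads = {
        lib: LIBRARY_COUNTS[lib]["insertion_reads"]
        - LIBRARY_COUNTS[lib]["insertion_regions"]
        for lib in LIBRARIES
    }
    singles_by_lib: dict[str, list[int]] = {}
    for idx, libs in enumerate(members):
        if len(libs) == 1:
            singles_by_lib.setdefault(libs[0], []).append(idx)
    quota = CLUSTER_COUNTS["n_multi_read"] - n_multi_lib
    boosted: list[tuple[int, str]] = []
    # libraries with extra reads but no multi-library incidence need at
    # least one multi-read singleton to absorb them
    libs_in_multi = {lib for libs in members[:n_multi_lib] for lib in libs}
    for lib in sorted(LIBRARIES, key=lambda l: -extra_reads[l]):
        if extra_reads[lib] > 0 and lib not in libs_in_multi and quota > 0:
            idx = singles_by_lib[lib].pop()
            counts[idx][lib] += 1
            extra_reads[lib] -= 1
            boosted.append((idx, lib))
            quota -= 1
    for lib in sorted(LIBRARIES, key=lambda l: -extra_reads[l]):
        while quota > 0 and extra_reads[lib] > 0 and singles_by_lib.get(lib):
            idx = singles_by_lib[lib].pop()
            counts[idx][lib] += 1
            extra_reads[lib] -= 1
            boosted.append((idx, lib))
            quota -= 1
    assert quota == 0, "could not reach the multi-read cluster count"
    # remaining extras go to multi-library incidences (already multi-read),
    # falling back to this library's boosted singletons
    multi_incidences = {
        lib: [i for i in range(n_multi_lib) if lib in members[i]] for lib in LIBRARIES
    }
    for lib in LIBRARIES:
        slots = multi_incidences[lib] or [i for i, l in boosted if l == lib]
        assert slots, f"library {lib} has nowhere to absorb extra reads"
        j = 0
        while extra_reads[lib] > 0:
            counts[slots[j % len(slots)]][lib] += 1
            extra_reads[lib] -= 1
            j += 1

    clusters: list[InsertionCluster] = []
    n_known = CLUSTER_COUNTS["n_clusters"] - CLUSTER_COUNTS["n_novel"]
    n_intronic = CLUSTER_COUNTS["n_intronic"]
    rid = 0
    for idx, c in enumerate(counts):
        read_ids = []
        for lib in sorted(c):
            for _ in range(c[lib]):
                rid += 1
                read_ids.append(f"x{rid:05d}")
        clusters.append(
            InsertionCluster(
                cluster_id=f"cl{idx + 1:05d}",
                chrom="chrT",
                breakpoint_lo=1000 * (idx + 1),
                breakpoint_hi=1000 * (idx + 1),
                read_ids=read_ids,
                library_counts=dict(c),
                novel=idx >= n_known,
                genic_context="intronic" if idx < n_intronic else "intergenic",
            )
        )
    return clusters
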