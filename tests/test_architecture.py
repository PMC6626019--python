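"""Overlap resolution, protein classification and synergy typing."""

import itertools

import numpy as np
import pytest

from glycoscan import (
    FamilyCatalog,
    InputError,
    build_architectures,
    classify,
    classify_synergy,
    resolve_overlaps,
)
from glycoscan.scan import DomainHit


def hit(fam, start, end, bits, acc=None, pid="p1", evalue=1e-10):
    cat = FamilyCatalog.default()
    if acc is None:
        entry = cat.by_family(fam)
        acc = entry.accession if entry else f"UNK_{fam}"
    return DomainHit(pid, acc, fam, start, end, bits, evalue)


@pytest.fixture(scope="module")
def catalog():
    return FamilyCatalog.default()


class TestResolveOverlaps:
    def test_large_overlap_keeps_stronger(self):
        a = hit("GH5", 10, 100, 50.0)
        b = hit("GH10", 15, 95, 30.0)
        assert resolve_overlaps([a, b], 0.5) == [a]

    def test_small_overlap_keeps_both(self):
        a = hit("GH5", 10, 100, 50.0)
        c = hit("GH10", 96, 180, 30.0)
        assert resolve_overlaps([a, c], 0.5) == [a, c]

    def test_mixed_proteins_rejected(self):
        with pytest.raises(InputError, match="multiple proteins"):
            resolve_overlaps([hit("GH5", 1, 10, 5.0, pid="a"),
                              hit("GH5", 1, 10, 5.0, pid="b")])

    def test_greedy_invariant_on_random_intervals(self):
        """Output equals an independent re-application of the greedy rule."""
        rng = np.random.default_rng(17)
        fams = ["GH5", "GH10", "GH18", "CBM2", "Dockerin", "Fn3"]
        for _ in range(50):
            hits = []
            for f in rng.permutation(fams):
                s = int(rng.integers(1, 150))
                e = s + int(rng.integers(5, 80))
                hits.append(hit(str(f), s, e, float(rng.integers(5, 90))))
            tol = float(rng.choice([0.0, 0.3, 0.5]))
            kept = resolve_overlaps(hits, tol)
            # independent check: walk hits in score order, apply the rule
            order = sorted(hits, key=lambda h: (-h.bit_score, h.evalue,
                                                h.ali_start, h.accession))
            expected = []
            for h in order:
                if all(
                    min(h.ali_end, k.ali_end) - max(h.ali_start, k.ali_start) + 1
                    <= tol * min(h.length, k.length)
                    for k in expected
                ):
                    expected.append(h)
            assert sorted(kept, key=lambda h: h.ali_start) == sorted(
                expected, key=lambda h: h.ali_start
            )
            # and the result is sorted by start
            assert [h.ali_start for h in kept] == sorted(h.ali_start for h in kept)


class TestClassify:
    def test_single_gh_is_sdgh(self, catalog):
        label, repeats = classify([hit("GH5", 10, 100, 50.0)], catalog)
        assert label == "SDGH" and repeats == {}

    def test_gh5_gh10_is_magh(self, catalog):
        """A cellulase + xylanase two-domain protein is multi-activity."""
        domains = [hit("GH5", 10, 100, 50.0), hit("GH10", 120, 220, 45.0)]
        label, _ = classify(domains, catalog)
        assert label == "MAGH"

    def test_gh9_cbm3_dockerin_is_mdgh_not_magh(self, catalog):
        """GH + binding module + dockerin: multi-domain, single activity."""
        domains = [
            hit("GH9", 10, 300, 90.0),
            hit("CBM3", 320, 420, 30.0),
            hit("Dockerin", 440, 500, 20.0),
        ]
        label, _ = classify(domains, catalog)
        assert label == "MDGH"

    def test_four_gh5_repeat_is_magh(self, catalog):
        domains = [hit("GH5", 1 + 200 * i, 150 + 200 * i, 50.0) for i in range(4)]
        label, repeats = classify(domains, catalog)
        assert label == "MAGH"
        assert repeats == {"GH5": 4}

    def test_accessory_only_is_non_gh(self, catalog):
        domains = [hit("CBM2", 1, 60, 20.0), hit("Fn3", 80, 160, 18.0)]
        label, _ = classify(domains, catalog)
        assert label == "non_GH"

    def test_unknown_accession_degrades_with_warning(self, catalog):
        warnings = []
        domains = [hit("GH5", 1, 100, 50.0),
                   DomainHit("p1", "PF99999", "Mystery", 120, 200, 30.0, 1e-8)]
        label, _ = classify(domains, catalog, warnings)
        assert label == "MDGH"  # mystery domain treated as accessory
        assert warnings and "PF99999" in warnings[0]

    def test_order_and_translation_invariance(self, catalog):
        domains = [hit("GH5", 10, 100, 50.0), hit("CBM2", 150, 210, 25.0)]
        shuffled = list(reversed(domains))
        shifted = [hit("GH5", 1010, 1100, 50.0), hit("CBM2", 1150, 1210, 25.0)]
        assert classify(domains, catalog) == classify(shuffled, catalog)
        assert classify(domains, catalog) == classify(shifted, catalog)


class TestSynergy:
    def test_cellulase_xylanase_is_parallel_pathway(self, catalog):
        domains = [hit("GH5", 10, 100, 50.0), hit("GH10", 120, 220, 45.0)]
        calls = classify_synergy(domains, catalog)
        assert calls == [(("GH10", "GH5"), "PPS")]

    @pytest.mark.parametrize("xylanase", ["GH10", "GH11"])
    @pytest.mark.parametrize("esterase", ["Polysacc_deac_1", "Esterase"])
    def test_xylanase_esterase_is_debranching(self, catalog, xylanase, esterase):
        domains = [hit(xylanase, 10, 100, 50.0), hit(esterase, 120, 200, 30.0)]
        calls = classify_synergy(domains, catalog)
        assert calls == [(tuple(sorted((xylanase, esterase))), "DS")]

    def test_backbone_plus_oligosaccharidase_is_linear_pathway(self, catalog):
        domains = [hit("GH5", 10, 100, 50.0), hit("GH3", 120, 260, 40.0)]
        calls = classify_synergy(domains, catalog)
        assert calls == [(("GH3", "GH5"), "LPS")]

    def test_same_family_repeat_is_none(self, catalog):
        domains = [hit("GH5", 10, 100, 50.0), hit("GH5", 150, 240, 48.0)]
        calls = classify_synergy(domains, catalog)
        assert calls == [(("GH5", "GH5"), "none")]

    def test_non_magh_input_rejected(self, catalog):
        with pytest.raises(InputError):
            classify_synergy([hit("GH5", 10, 100, 50.0)], catalog)


class TestBuildArchitectures:
    def test_arch_string_and_order(self, catalog):
        hits = [
            hit("GH10", 120, 220, 45.0),
            hit("GH5", 10, 100, 50.0),
        ]
        archs = build_architectures(hits, catalog)
        assert len(archs) == 1
        assert archs[0].arch_string == "GH5-GH10"
        assert archs[0].class_label == "MAGH"
        assert archs[0].synergy_calls == [(("GH10", "GH5"), "PPS")]

    def test_empty_input(self, catalog):
        assert build_architectures([], catalog) == []

    def test_input_order_invariance(self, catalog):
        hits = [
            hit("GH9", 10, 300, 90.0),
            hit("CBM3", 320, 420, 30.0),
            hit("Dockerin", 440, 500, 20.0),
        ]
        for perm in itertools.permutations(hits):
            archs = build_architectures(list(perm), catalog)
            assert archs[0].arch_string == "GH9-CBM3-Dockerin"
            assert archs[0].class_label == "MDGH"

    def test_sdgh_arch_string_has_no_dash(self, catalog):
        archs = build_architectures([hit("GH5", 10, 100, 50.0)], catalog)
        assert "-" not in archs[0].arch_string

    def test_partition_of_labels(self, catalog):
        """Every protein gets exactly one label; MAGH is a kind of MDGH."""
        rng = np.random.default_rng(9)
        fams = ["GH5", "GH10", "GH18", "GH3", "CBM2", "Dockerin", "Esterase"]
        hits = []
        for p in range(40):
            pos = 1
            for _ in range(int(rng.integers(1, 4))):
                f = fams[rng.integers(len(fams))]
                hits.append(hit(f, pos, pos + 90, float(rng.integers(20, 80)),
                                pid=f"p{p:03d}"))
                pos += 120
        archs = build_architectures(hits, catalog)
        labels = [a.class_label for a in archs]
        assert all(l in ("SDGH", "MDGH", "MAGH", "non_GH") for l in labels)
        n_mdgh_incl = sum(a.is_mdgh for a in archs)
        assert labels.count("MAGH") <= n_mdgh_incl
        assert len(archs) == len({a.protein_id for a in archs})
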