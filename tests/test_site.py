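"""Active-site extraction: filters, guide selection, geometry, alignment."""

import numpy as np
import pytest

import ascsite as asc
from ascsite._alphabet import AA20
from ascsite.cv import pairwise_identity
from ascsite.io import EmptyResultError, LabelledFamily, Residue, TemplateStructure
from ascsite.site import core_score_proxy, template_column_map


def _family(rows, labels=None, template_id=None, **kw):
    ids = [f"s{i}" for i in range(len(rows))]
    if template_id is not None:
        ids[0] = template_id
    return LabelledFamily(ids=ids, rows=rows, labels=labels or {},
                          template_id=template_id, **kw)


class TestTemplateIdentityFilter:
    def test_low_identity_row_removed(self):
        fam = LabelledFamily(
            ids=["T", "same", "half", "low"],
            rows=["AAAAAAAAAA", "AAAAAAAAAA", "AAAAACCCCC", "CCCCCCCCCA"],
            labels={"same": "x", "half": "x", "low": "y"},
            template_id="T",
        )
        out = asc.filter_by_template_identity(fam, min_identity=0.2)
        assert out.ids == ["T", "same", "half"]

    def test_zero_threshold_is_identity_operation(self, fixture_bundle):
        family = fixture_bundle[0]
        out = asc.filter_by_template_identity(family, min_identity=0.0)
        assert out.ids == family.ids

    def test_template_always_retained(self):
        fam = LabelledFamily(
            ids=["T", "a"], rows=["AAAA", "AAAA"], labels={"a": "x"},
            template_id="T",
        )
        # template trivially identical to itself; filter keeps it at any bar
        out = asc.filter_by_template_identity(fam, min_identity=1.0)
        assert "T" in out.ids

    def test_all_labelled_removed_is_empty_result(self):
        fam = LabelledFamily(
            ids=["T", "a"], rows=["AAAAA", "CCCCC"], labels={"a": "x"},
            template_id="T",
        )
        with pytest.raises(EmptyResultError, match="no trainable"):
            asc.filter_by_template_identity(fam, min_identity=0.9)

    def test_matches_brute_force_identity_scan(self, fixture_bundle):
        family = fixture_bundle[0]
        threshold = 0.8
        out = asc.filter_by_template_identity(family, min_identity=threshold)
        template_row = family.row(family.template_id)
        expected = [
            i for i in family.ids
            if i == family.template_id
            or pairwise_identity(family.row(i), template_row) >= threshold
        ]
        assert out.ids == expected


class TestGuideSelection:
    def test_small_class_returned_whole(self):
        fam = _family(["AAAA", "AACC", "CCCC"],
                      labels={"s0": "x", "s1": "x", "s2": "x"})
        assert asc.select_guide_sequences(fam, n_per_class=5) == ["s0", "s1", "s2"]

    def test_identical_sequences_deterministic(self):
        rows = ["AAAA"] * 6
        fam = _family(rows, labels={f"s{i}": "x" for i in range(6)})
        first = asc.select_guide_sequences(fam, n_per_class=3)
        assert first == asc.select_guide_sequences(fam, n_per_class=3)
        assert first[0] == "s0"  # lexicographic seed among ties

    def test_empty_class_rejected(self):
        fam = _family(["AAAA"], labels={})
        fam.labels = {}
        with pytest.raises(ValueError):
            fam2 = LabelledFamily(ids=["a"], rows=["AAAA"], labels={"a": "x"})
            fam2.labels["ghost"] = "y"  # class with no actual rows
            asc.select_guide_sequences(fam2)

    def test_greedy_beats_random_subsets(self):
        rng = np.random.default_rng(19)
        rows = ["".join(rng.choice(list(AA20), size=30)) for _ in range(20)]
        fam = _family(rows, labels={f"s{i}": "x" for i in range(20)})
        picked = asc.select_guide_sequences(fam, n_per_class=5)
        idx = [fam.ids.index(i) for i in picked]
        from ascsite.cv import identity_matrix

        dist = 1.0 - identity_matrix(rows)

        def min_pair(sub):
            sub = list(sub)
            return min(dist[a, b] for i, a in enumerate(sub)
                       for b in sub[i + 1:])

        greedy_score = min_pair(idx)
        wins = 0
        trials = 1000
        for _ in range(trials):
            sub = rng.choice(20, size=5, replace=False)
            if greedy_score >= min_pair(sub):
                wins += 1
        assert wins / trials >= 0.95


class TestSiteAtoms:
    def test_het_group_atoms(self, three_res_het_pdb):
        st = asc.read_structure(three_res_het_pdb)
        pts = asc.site_atoms(st, asc.ActiveSiteSelector.het_group("IPM"))
        assert pts.shape == (4, 3)

    def test_coordinates_passthrough(self, three_res_het_pdb):
        st = asc.read_structure(three_res_het_pdb)
        sel = asc.ActiveSiteSelector.coordinates([[0.0, 0.0, 0.0]])
        np.testing.assert_array_equal(asc.site_atoms(st, sel),
                                      [[0.0, 0.0, 0.0]])

    def test_residue_selector(self, three_res_pdb):
        st = asc.read_structure(three_res_pdb)
        pts = asc.site_atoms(st, asc.ActiveSiteSelector.residue("A:ALA2"))
        assert pts.shape == (3, 3)
        pts2 = asc.site_atoms(st, asc.ActiveSiteSelector.residue("A:2"))
        np.testing.assert_array_equal(pts, pts2)

    def test_het_in_both_chains_of_dimer(self, tmp_path):
        text = (
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    2  C1  SUB A 900       1.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    3  C2  SUB A 900       1.500   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      4  CA  ALA B   1       9.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    5  C1  SUB B 900       8.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    6  C2  SUB B 900       8.500   0.000   0.000"
            "  1.00  0.00           C\nEND\n"
        )
        p = tmp_path / "dimer.pdb"
        p.write_text(text)
        st = asc.read_structure(p)
        pts = asc.site_atoms(st, asc.ActiveSiteSelector.het_group("SUB"))
        assert pts.shape == (4, 3)  # copies from both chains

    def test_unknown_name_lists_available(self, three_res_het_pdb):
        st = asc.read_structure(three_res_het_pdb)
        with pytest.raises(ValueError, match="IPM"):
            asc.site_atoms(st, asc.ActiveSiteSelector.het_group("ATP"))

    def test_empty_coordinate_selector_rejected(self):
        with pytest.raises(ValueError):
            asc.ActiveSiteSelector.coordinates([])


def _line_structure(seq, positions, chain="A"):
    """Single-CA-per-residue structure with explicit coordinates."""
    residues = []
    from ascsite._alphabet import ONE_TO_THREE

    for k, (aa, xyz) in enumerate(zip(seq, positions), start=1):
        residues.append(Residue(chain=chain, number=k, icode="",
                                name=ONE_TO_THREE[aa],
                                atoms=(("CA", *xyz),)))
    return TemplateStructure(
        chains=[chain], residues=residues, het_groups=[],
        sequence_per_chain={chain: seq},
        residue_index={chain: residues},
    )


class TestExtraction:
    def test_distance_cutoff_boundary(self):
        st = _line_structure("ACD", [(3.0, 0, 0), (5.9, 0, 0), (6.1, 0, 0)])
        fam = LabelledFamily(ids=["T", "a", "b"],
                             rows=["ACD", "ACD", "ACD"],
                             labels={"a": "x", "b": "y"}, template_id="T",
                             core_scores=np.array([9.0, 9.0, 9.0]))
        sel = asc.ActiveSiteSelector.coordinates([[0.0, 0.0, 0.0]])
        d = asc.extract_signature_positions(st, sel, fam, cutoff=6.0,
                                            core_min=5.0)
        assert [p.residue_id for p in d.positions] == ["A:ALA1", "A:CYS2"]
        assert d.positions[0].distance == pytest.approx(3.0)

    def test_core_score_threshold(self):
        st = _line_structure("AC", [(3.0, 0, 0), (4.0, 0, 0)])
        fam = LabelledFamily(ids=["T", "a"], rows=["AC", "AC"],
                             labels={"a": "x"}, template_id="T",
                             core_scores=np.array([9.0, 2.0]))
        sel = asc.ActiveSiteSelector.coordinates([[0.0, 0.0, 0.0]])
        d = asc.extract_signature_positions(st, sel, fam, cutoff=6.0,
                                            core_min=5.0)
        assert [p.column for p in d.positions] == [0]

    def test_selector_residue_excluded_from_signature(self):
        st = _line_structure("ACD", [(0.0, 0, 0), (2.0, 0, 0), (4.0, 0, 0)])
        fam = LabelledFamily(ids=["T"], rows=["ACD"], labels={},
                             template_id="T",
                             core_scores=np.full(3, 9.0))
        sel = asc.ActiveSiteSelector.residue("A:1")
        d = asc.extract_signature_positions(st, sel, fam, cutoff=6.0,
                                            core_min=0.0)
        assert 0 not in [p.column for p in d.positions]

    def test_zero_positions_is_empty_result(self, fixture_bundle):
        family, _, structure, selector = fixture_bundle
        with pytest.raises(EmptyResultError, match="cutoff"):
            asc.extract_signature_positions(structure, selector, family,
                                            cutoff=1.0)

    def test_monotone_in_cutoff_and_core_min(self, fixture_bundle):
        family, _, structure, selector = fixture_bundle
        prev: set = set()
        for cutoff in (4.0, 6.0, 12.0, 25.0):
            d = asc.extract_signature_positions(structure, selector, family,
                                                cutoff=cutoff, core_min=5.0)
            cols = set(d.columns)
            assert prev <= cols
            prev = cols
        strict = asc.extract_signature_positions(structure, selector, family,
                                                 cutoff=6.0, core_min=9.0)
        loose = asc.extract_signature_positions(structure, selector, family,
                                                cutoff=6.0, core_min=0.0)
        assert set(strict.columns) <= set(loose.columns)

    def test_rigid_motion_invariance(self, fixture_bundle, default_spec):
        family, truth, structure, selector = fixture_bundle
        rng = np.random.default_rng(4)
        # random rotation (QR of gaussian) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(scale=30.0, size=3)

        def move(res):
            pts = np.array([a[1:] for a in res.atoms])
            moved = pts @ q.T + t
            return Residue(res.chain, res.number, res.icode, res.name,
                           tuple((a[0], *xyz) for a, xyz in
                                 zip(res.atoms, moved)))

        moved = TemplateStructure(
            chains=structure.chains,
            residues=[move(r) for r in structure.residues],
            het_groups=[move(h) for h in structure.het_groups],
            sequence_per_chain=structure.sequence_per_chain,
            residue_index={
                c: [move(r) for r in structure.residue_index[c]]
                for c in structure.chains
            },
        )
        d1 = asc.extract_signature_positions(structure, selector, family)
        d2 = asc.extract_signature_positions(moved, selector, family)
        assert d1.columns == d2.columns
        np.testing.assert_allclose(
            [p.distance for p in d1.positions],
            [p.distance for p in d2.positions], atol=1e-8,
        )

    def test_template_mismatch_rejected(self, fixture_bundle):
        family, _, structure, selector = fixture_bundle
        rows = list(family.rows)
        # corrupt >5% of the template row's residues
        t_idx = family.ids.index(family.template_id)
        row = list(rows[t_idx])
        for c in range(0, 10):
            row[c] = "W" if row[c] != "W" else "Y"
        rows[t_idx] = "".join(row)
        bad = LabelledFamily(ids=family.ids, rows=rows, labels=family.labels,
                             template_id=family.template_id,
                             core_scores=family.core_scores)
        with pytest.raises(ValueError, match="mismatch"):
            template_column_map(structure, bad)


class TestMapSignatures:
    def test_template_row_reproduces_template_residues(self, signature_bundle):
        family, _, definition, sigset = signature_bundle
        tmpl_sig = sigset.signature(family.template_id)
        from ascsite._alphabet import THREE_TO_ONE

        expected = "".join(
            THREE_TO_ONE[p.residue_id.split(":")[1][:3]]
            for p in definition.positions
        )
        assert tmpl_sig == expected

    def test_all_gap_row(self, signature_bundle):
        family, _, definition, _ = signature_bundle
        fam2 = LabelledFamily(
            ids=family.ids + ["gappy"],
            rows=family.rows + ["-" * family.width],
            labels=family.labels, template_id=family.template_id,
            core_scores=family.core_scores,
        )
        sigset = asc.map_signatures(fam2, definition)
        assert sigset.signature("gappy") == "-" * len(definition)

    def test_matches_column_lookup_oracle(self, signature_bundle):
        family, _, definition, sigset = signature_bundle
        for sid, sig in zip(sigset.ids, sigset.signatures):
            row = family.row(sid)
            assert sig == "".join(row[c] for c in definition.columns)

    def test_out_of_range_columns_rejected(self, signature_bundle):
        family, _, definition, _ = signature_bundle
        narrow = LabelledFamily(ids=["a"], rows=["ACD"], labels={})
        with pytest.raises(ValueError, match="width"):
            asc.map_signatures(narrow, definition)


class TestCoreProxy:
    def test_conserved_scores_above_variable(self):
        rows = ["AAAC", "AAAD", "AAAG", "AAAW"]
        fam = _family(rows)
        scores = core_score_proxy(fam)
        assert scores.shape == (4,)
        assert (scores[:3] > scores[3]).all()
        assert scores.min() >= 0 and scores.max() <= 9

    def test_fully_conserved_msa_maps_to_nine(self):
        fam = _family(["AAAA", "AAAA", "AAAA"])
        np.testing.assert_allclose(core_score_proxy(fam), 9.0)


class TestAlignToGuide:
    def _guide(self, rows, template_id="T"):
        ids = [template_id] + [f"g{i}" for i in range(1, len(rows))]
        return LabelledFamily(ids=ids, rows=rows, labels={},
                              template_id=template_id)

    def test_identical_ungapped_row_reproduced(self, clean_bundle):
        family = clean_bundle[0]
        guide = family
        sid = family.labelled_ids[0]
        raw = family.row(sid).replace("-", "")
        aligned = asc.align_to_guide(guide, raw)
        assert aligned == family.row(sid)

    def test_single_deletion_adds_one_gap(self):
        guide = self._guide(["MKVLITAGAKQW", "MKVLITAGAKQW"])
        raw = "MKVLITAGAKQW".replace("G", "", 1)
        aligned = asc.align_to_guide(guide, raw, min_template_identity=0.1)
        assert len(aligned) == 12
        assert aligned.count("-") == 1
        # all other columns keep their residues
        kept = [a for a in aligned if a != "-"]
        assert "".join(kept) == raw

    def test_empty_guide_rejected(self):
        empty = LabelledFamily(ids=[], rows=[], labels={})
        with pytest.raises(ValueError, match="empty guide"):
            asc.align_to_guide(empty, "ACDEFG")

    def test_low_identity_query_rejected(self):
        guide = self._guide(["WWWWWWWWWW", "WWWWWWWWWW"])
        with pytest.raises(ValueError, match="identity"):
            asc.align_to_guide(guide, "AAAAAAAAAA")

    def test_optimal_score_matches_exhaustive_enumeration(self):
        from ascsite.io import load_matrix
        from ascsite._alphabet import NULL_IDX, encode_rows

        rng = np.random.default_rng(8)
        guide_rows = ["MKVLWAC-", "MKVLYACD"]
        guide = self._guide(guide_rows)
        matrix = load_matrix("BLOSUM62").reordered(AA20)
        codes = encode_rows(guide_rows)
        width = codes.shape[1]
        profile = np.zeros((width, 20))
        for col in range(width):
            res = codes[:, col][codes[:, col] != NULL_IDX]
            if len(res):
                profile[col] = matrix.values[res].mean(axis=0)

        open_, ext = 10.0, 1.0

        def oracle(i, j, raw, last):
            """Exhaustive recursion over (match, skip-column, insert)."""
            if i == len(guide_rows[0]) and j == len(raw):
                return 0.0
            best = -np.inf
            if i < width and j < len(raw):
                aa = AA20.index(raw[j]) if raw[j] in AA20 else None
                s = profile[i][aa] if aa is not None else 0.0
                best = max(best, s + oracle(i + 1, j + 1, raw, "M"))
            if i < width:
                pen = ext if last == "D" else open_
                best = max(best, -pen + oracle(i + 1, j, raw, "D"))
            if j < len(raw):
                pen = ext if last == "I" else open_
                best = max(best, -pen + oracle(i, j + 1, raw, "I"))
            return best

        for _ in range(5):
            n = int(rng.integers(4, 9))
            raw = "".join(rng.choice(list("MKVLWYACD"), size=n))
            _, score = asc.align_to_guide(
                guide, raw, min_template_identity=0.0, return_score=True
            )
            assert score == pytest.approx(oracle(0, 0, raw, "start"))
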