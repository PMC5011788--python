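"""Directory-structure generation, task counting and batch ctl edits."""

import os

import pytest

from codemlbatch import identity, scaffold
from codemlbatch.errors import ValidationError
from codemlbatch.scaffold import (build_structure, edit_controls,
                                  expected_task_count, load_manifest,
                                  parse_task_dir, task_rel_dir)
from codemlbatch.templates import GridSpec, read_ctl, templates_for_class
from conftest import scan_dataset


def _pairs(example_dataset, request_):
    msas, trees = scan_dataset(example_dataset)
    return identity.pair_inputs(msas, trees, request_)


class TestBuildStructure:
    def test_s_pair_yields_sites_plus_m8a(self, example_dataset, tmp_path):
        req = identity.parse_model_spec("s")
        pairs = _pairs(example_dataset, req)[:1]
        tasks = build_structure(pairs, req, GridSpec(kappas=(2,), omegas=(0.5,)),
                                tmp_path, "job")
        assert sorted(t.template for t in tasks) == ["SM-M8a", "SM-sites"]

    def test_b_pair_three_templates(self, example_dataset, tmp_path):
        req = identity.parse_model_spec("b")
        pairs = _pairs(example_dataset, req)[:1]
        tasks = build_structure(pairs, req, GridSpec(kappas=(2,), omegas=(0.5,)),
                                tmp_path, "job")
        assert sorted(t.template for t in tasks) == ["BM-M0", "BM-TrC", "BM-TrU"]

    def test_w_and_c_pairs_with_2x2_grid(self, example_dataset, tmp_path):
        req = identity.parse_model_spec("w,c")
        msas, trees = scan_dataset(example_dataset)
        pairs = identity.pair_inputs(msas[:1], trees, req)
        assert len(pairs) == 2
        grid = GridSpec(kappas=(2, 4), omegas=(0.5, 1.5))
        tasks = build_structure(pairs, req, grid, tmp_path, "job")
        assert len(tasks) == (2 + 2) * 4

    def test_count_matches_brute_force_on_random_requests(
            self, example_dataset, tmp_path, rng):
        msas, trees = scan_dataset(example_dataset)
        specs = ["s", "b", "s[8a],b", "s[0:3],w", "s,b,c,w", "w,c", "s[7:8],c"]
        for i, spec in enumerate(specs):
            req = identity.parse_model_spec(spec)
            pairs = identity.pair_inputs(msas, trees, req)
            grid = GridSpec(kappas=tuple(rng.uniform(1, 5) for _ in range(rng.randint(1, 3))),
                            omegas=tuple(rng.uniform(0.1, 2) for _ in range(rng.randint(1, 3))))
            tasks = build_structure(pairs, req, grid, tmp_path, f"job{i}")
            brute = 0
            for p in pairs:
                for _t in templates_for_class(p.letter, req):
                    for _k in grid.kappas:
                        for _w in grid.omegas:
                            brute += 1
            assert len(tasks) == brute == expected_task_count(pairs, req, grid)

    def test_ctl_references_existing_inputs(self, example_dataset, tmp_path,
                                            full_request, tiny_grid):
        pairs = _pairs(example_dataset, full_request)
        tasks = build_structure(pairs, full_request, tiny_grid, tmp_path, "job")
        root = tmp_path / "job"
        for t in tasks[:5]:
            cf = read_ctl(root / t.task_dir / "codeml.ctl")
            task_dir = root / t.task_dir
            assert (task_dir / cf.params["seqfile"]).resolve().exists()
            assert (task_dir / cf.params["treefile"]).resolve().exists()

    def test_collision_rejected_without_resume(self, example_dataset, tmp_path,
                                               full_request, tiny_grid):
        pairs = _pairs(example_dataset, full_request)[:1]
        build_structure(pairs, full_request, tiny_grid, tmp_path, "job")
        with pytest.raises(ValidationError, match="exists"):
            build_structure(pairs, full_request, tiny_grid, tmp_path, "job")
        build_structure(pairs, full_request, tiny_grid, tmp_path, "job",
                        resume=True)   # resume allowed

    def test_taxa_mismatch_skips_pair_with_warning(self, example_dataset,
                                                   tmp_path, tiny_grid):
        req = identity.parse_model_spec("b")
        msas, trees = scan_dataset(example_dataset)
        bad_tree = tmp_path / "X1_b.nwk"
        bad_tree.write_text("(Z1,(Z2,Z3)#1,Z4);")
        trees = [identity.parse_tree_filename("X1_b.nwk", path=str(bad_tree))]
        pairs = identity.pair_inputs(msas[:1], trees, req)
        warnings = []
        tasks = build_structure(pairs, req, tiny_grid, tmp_path, "job",
                                warnings=warnings)
        assert tasks == []
        assert any("mismatch" in w for w in warnings)

    def test_rebuild_is_idempotent(self, example_dataset, tmp_path,
                                   full_request, tiny_grid):
        pairs = _pairs(example_dataset, full_request)
        build_structure(pairs, full_request, tiny_grid, tmp_path, "job")
        snapshot = {}
        root = tmp_path / "job"
        for dirpath, _dirs, files in os.walk(root):
            for f in files:
                p = os.path.join(dirpath, f)
                snapshot[p] = open(p, "rb").read()
        build_structure(pairs, full_request, tiny_grid, tmp_path, "job",
                        resume=True)
        for p, content in snapshot.items():
            assert open(p, "rb").read() == content


class TestPathBijection:
    def test_roundtrip(self):
        rel = task_rel_dir("ND4_L1", "H1", "w", "BSM-MA", 2.0, 0.5)
        meta = parse_task_dir(rel)
        assert meta == {"letter": "w", "gene": "ND4_L1", "tree_ref": "H1",
                        "template": "BSM-MA", "kappa": 2.0, "omega": 0.5}

    def test_manifest_agrees_with_paths(self, example_dataset, tmp_path,
                                        full_request, tiny_grid):
        pairs = _pairs(example_dataset, full_request)
        build_structure(pairs, full_request, tiny_grid, tmp_path, "job")
        for task in load_manifest(tmp_path / "job"):
            meta = parse_task_dir(task["task_dir"])
            for key in ("letter", "gene", "tree_ref", "template", "kappa", "omega"):
                assert meta[key] == task[key]


class TestEditControls:
    @pytest.fixture()
    def structure(self, example_dataset, tmp_path, tiny_grid):
        req = identity.parse_model_spec("b")
        pairs = _pairs(example_dataset, req)
        tasks = build_structure(pairs, req, tiny_grid, tmp_path, "job")
        return tmp_path / "job", tasks

    def test_edit_all(self, structure):
        root, tasks = structure
        n = edit_controls(root, {"cleandata": "1"})
        assert n == len(tasks)
        for t in tasks:
            assert read_ctl(root / t.task_dir / "codeml.ctl").params["cleandata"] == "1"

    def test_selector_matching_nothing(self, structure):
        root, _ = structure
        assert edit_controls(root, {"cleandata": "1"},
                             selector=lambda t: False) == 0

    def test_differential_edit(self, structure):
        root, tasks = structure
        edit_controls(root, {"cleandata": "1"},
                      selector=lambda t: t["template"] == "BM-M0")
        for t in tasks:
            val = read_ctl(root / t.task_dir / "codeml.ctl").params["cleandata"]
            assert val == ("1" if t.template == "BM-M0" else "0")

    def test_unknown_key_rejected_unless_forced(self, structure):
        root, tasks = structure
        with pytest.raises(ValidationError, match="notakey"):
            edit_controls(root, {"notakey": "1"})
        assert edit_controls(root, {"notakey": "1"}, force=True) == len(tasks)

    def test_permissive_mode_handles_manifestless_tree(self, tmp_path):
        d = tmp_path / "manual" / "x"
        d.mkdir(parents=True)
        (d / "codeml.ctl").write_text("model = 0\ncleandata = 0\n")
        with pytest.raises(ValidationError):
            edit_controls(tmp_path / "manual", {"cleandata": "1"})
        assert edit_controls(tmp_path / "manual", {"cleandata": "1"},
                             permissive=True) == 1
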