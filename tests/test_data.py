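import numpy as np
import pytest

from tapb.bias import overall_tendency, sequence_tendency
from tapb.data import (
    DTIDataset,
    FormatError,
    InteractionRecord,
    SyntheticConfig,
    cross_domain_split,
    generate_synthetic,
    random_split,
    read_interactions,
    write_interactions,
)

from conftest import make_dataset


class TestReadWrite:
    def test_parse_default_header(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SMILES,Protein,Y\nCCN,ACDEF,1\nCCO,ACDEF,0\nCCC,MKLV,1\n")
        ds = read_interactions(path)
        assert len(ds) == 3
        assert ds.n_positives == 2
        assert ds.n_targets == 2  # identity is the exact sequence string
        assert ds.records[0].drug_id == "D0" and ds.records[2].drug_id == "D2"

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("smiles_str,Protein,Y\nCCN,ACDEF,1\n")
        with pytest.raises(FormatError, match="SMILES"):
            read_interactions(path)

    def test_non_binary_label_reports_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SMILES,Protein,Y\nCCN,ACDEF,1\nCCO,ACDEF,2\n")
        with pytest.raises(ValueError, match="row 1"):
            read_interactions(path)

    def test_conflicting_duplicate_rejected_unless_flagged(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("SMILES,Protein,Y\nCCN,ACDEF,1\nCCN,ACDEF,0\n")
        with pytest.raises(ValueError, match="conflicting"):
            read_interactions(path)
        assert len(read_interactions(path, allow_duplicates=True)) == 2

    def test_round_trip(self, tmp_path, synthetic_dataset):
        # the layout carries no id columns, so ids are first-seen
        # positional: content triples round-trip exactly, and a second
        # read reproduces the first one identically
        path = tmp_path / "rt.csv"
        write_interactions(synthetic_dataset, path)
        again = read_interactions(path)
        assert [(r.smiles, r.sequence, r.label) for r in again] == [
            (r.smiles, r.sequence, r.label) for r in synthetic_dataset
        ]
        write_interactions(again, path)
        assert read_interactions(path) == again

    def test_empty_write_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_interactions(DTIDataset([]), tmp_path / "x.csv")

    def test_custom_dialect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("smi,seq,lab\nCCN,ACDEF,1\n")
        ds = read_interactions(path, dialect={"smiles": "smi", "sequence": "seq", "label": "lab"})
        assert len(ds) == 1


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(smiles="", sequence="ACD", label=1),
            dict(smiles="CC", sequence="", label=0),
            dict(smiles="CC", sequence="ACD", label=2),
        ],
    )
    def test_invalid_fields_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InteractionRecord(drug_id="d", target_id="t", **kwargs)


class TestRandomSplit:
    def test_ratio_sizes(self, synthetic_dataset):
        ds = synthetic_dataset.subset(range(100))
        train, valid, test = random_split(ds, (7, 1, 2), seed=0)
        assert (len(train), len(valid), len(test)) == (70, 10, 20)

    def test_is_partition(self, synthetic_dataset):
        train, valid, test = random_split(synthetic_dataset, (7, 1, 2), seed=3)
        merged = sorted(
            (r.drug_id, r.target_id) for part in (train, valid, test) for r in part
        )
        assert merged == sorted((r.drug_id, r.target_id) for r in synthetic_dataset)

    def test_deterministic(self, synthetic_dataset):
        a = random_split(synthetic_dataset, (7, 1, 2), seed=5)
        b = random_split(synthetic_dataset, (7, 1, 2), seed=5)
        assert all(x == y for x, y in zip(a, b))

    def test_zero_ratio_needs_flag(self, synthetic_dataset):
        with pytest.raises(ValueError):
            random_split(synthetic_dataset, (1, 0, 0), seed=0)
        train, valid, test = random_split(synthetic_dataset, (1, 0, 0), seed=0, allow_zero=True)
        assert len(valid) == len(test) == 0 and len(train) == len(synthetic_dataset)

    def test_too_small(self):
        with pytest.raises(ValueError):
            random_split(make_dataset([(0, 0, 1), (1, 1, 0)]), (7, 1, 2), seed=0)


class TestCrossDomainSplit:
    def test_entity_pools_disjoint(self, synthetic_dataset):
        source, target = cross_domain_split(synthetic_dataset, 0.6, seed=1)
        assert not set(source.drug_index) & set(target.drug_index)
        assert not set(source.target_index) & set(target.target_index)

    def test_no_pairs_invented(self, synthetic_dataset):
        source, target = cross_domain_split(synthetic_dataset, 0.6, seed=1)
        assert len(source) + len(target) <= len(synthetic_dataset)

    def test_degenerate_fraction_errors(self, synthetic_dataset):
        with pytest.raises(ValueError):
            cross_domain_split(synthetic_dataset, 1.0, seed=0)


class TestSyntheticGenerator:
    def test_deterministic(self):
        cfg = SyntheticConfig(n_drugs=30, n_targets=15, n_pairs=100, seed=11)
        assert generate_synthetic(cfg) == generate_synthetic(cfg)

    def test_pure_target_bias_drives_target_tendency(self):
        # propensity-only labels with fully extreme targets: the mean
        # target tendency must approach 1 - eps
        cfg = SyntheticConfig(
            n_drugs=100,
            n_targets=50,
            n_pairs=4000,
            target_bias=1.0,
            drug_bias=0.0,
            extreme_eps=0.01,
            mechanism_weight=0.0,
            seed=3,
        )
        ds = generate_synthetic(cfg)
        table = sequence_tendency(ds, "target")
        # independent direct computation of the expected tendency: each
        # target's labels are Bernoulli(theta/2 + theta_d/2) with
        # theta in {eps, 1-eps} and drug propensities centered at 0.5
        z_expected = np.mean(np.abs(table.z - 0.5)) + 0.5
        assert overall_tendency(table) == pytest.approx(z_expected)
        assert overall_tendency(table) > 0.68  # extreme-mixture bound at eps=0.01

    def test_target_axis_dominates_drug_axis(self):
        hits = 0
        for seed in range(20):
            cfg = SyntheticConfig(
                n_drugs=40, n_targets=20, n_pairs=300,
                target_bias=1.0, drug_bias=0.0, mechanism_weight=0.0, seed=seed,
            )
            ds = generate_synthetic(cfg)
            zt = overall_tendency(sequence_tendency(ds, "target"))
            zd = overall_tendency(sequence_tendency(ds, "drug"))
            hits += zt > zd
        assert hits == 20

    def test_infeasible_pair_count(self):
        with pytest.raises(ValueError):
            generate_synthetic(SyntheticConfig(n_drugs=5, n_targets=5, n_pairs=26))

    def test_no_duplicate_pairs(self, synthetic_dataset):
        pairs = [(r.drug_id, r.target_id) for r in synthetic_dataset]
        assert len(pairs) == len(set(pairs))
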