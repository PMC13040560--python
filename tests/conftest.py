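import json
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

from ontomap.fixtures import FixtureSpec, make_toy_map_and_records, make_toy_ontology

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=7)


@pytest.fixture
def toy_world_dir(tmp_path: Path, fixture_spec: FixtureSpec) -> Path:
    """Toy ontology + extended map + records + ground truth written to disk."""
    (tmp_path / "ontology.json").write_text(make_toy_ontology(fixture_spec))
    map_tsv, records_csv, truth = make_toy_map_and_records(fixture_spec)
    (tmp_path / "map.tsv").write_text(map_tsv)
    (tmp_path / "records.csv").write_text(records_csv)
    (tmp_path / "ground_truth.jsonl").write_text(
        "".join(json.dumps(t, sort_keys=True) + "\n" for t in truth)
    )
    accept_rows = [
        {"source_text": t["code_raw"], "target_label": t["target_label"]}
        for t in truth
        if t["kind"] == "pivot"
    ]
    pd.DataFrame(accept_rows).to_csv(tmp_path / "accept.csv", index=False)
    return tmp_path


@pytest.fixture
def ground_truth(toy_world_dir: Path) -> list[dict]:
    return [
        json.loads(line)
        for line in (toy_world_dir / "ground_truth.jsonl").read_text().splitlines()
    ]
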