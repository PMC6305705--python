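import numpy as np
import pytest

from darkmeter.config import Config
from darkmeter.refdb import ReferenceDB, RefTip


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_db(newick: str, seqs: dict[str, str], copies: dict[str, int] | None = None,
            domains: dict[str, str] | None = None) -> ReferenceDB:
    tips = {}
    for tip_id, seq in seqs.items():
        tips[tip_id] = RefTip(
            tip_id=tip_id,
            sequence=seq,
            copy_number=(copies or {}).get(tip_id, 1),
            domain=(domains or {}).get(tip_id, "Bacteria"),
            lineage="Bacteria;test",
        )
    return ReferenceDB.from_newick(newick, tips)


@pytest.fixture
def config():
    return Config()


@pytest.fixture
def four_tip_db():
    """((A,B),(C,D)) with distinctive sequences and copy numbers."""
    rng = np.random.default_rng(42)
    base = random_seq(rng, 400)
    seqs = {}
    for i, tip in enumerate("ABCD"):
        arr = np.array(list(base))
        sites = rng.choice(400, size=60 * (i + 1) % 180 + 40, replace=False)
        for s in sites:
            arr[s] = rng.choice([b for b in "ACGT" if b != arr[s]])
        seqs[tip] = "".join(arr)
    return make_db(
        "((A:0.1,B:0.1)n1:0.1,(C:0.1,D:0.1)n2:0.1)root;",
        seqs,
        copies={"A": 2, "B": 4, "C": 7, "D": 1},
        domains={"A": "Bacteria", "B": "Bacteria", "C": "Archaea", "D": "Archaea"},
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One shared small end-to-end run for conservation/summary checks."""
    from darkmeter.pipeline import run_all
    from darkmeter.synth import SynthParams

    out = tmp_path_factory.mktemp("pipeline")
    params = SynthParams(
        n_refs=12, n_dark=9, n_in_db=9, n_samples=6, mean_abundance=40, seed=11
    )
    manifest = run_all(Config(seed=11), out, synth_params=params)
    return out, manifest
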