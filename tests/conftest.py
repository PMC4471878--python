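import numpy as np
import pytest

from mirsponge import MatureMiRNA, Registry

RNA = "ACGU"


def random_mirna(rng: np.random.Generator, mirna_id: str,
                 length_range: tuple[int, int] = (18, 25)) -> MatureMiRNA:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return MatureMiRNA(mirna_id, "".join(rng.choice(list(RNA), size=length)))


def random_registry(rng: np.random.Generator, n: int,
                    length_range: tuple[int, int] = (18, 25)) -> Registry:
    return Registry(random_mirna(rng, f"rnd-miR-{i}", length_range)
                    for i in range(1, n + 1))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def let7() -> MatureMiRNA:
    # dme-let-7-5p mature sequence; seed GAGGUAG
    return MatureMiRNA("dme-let-7-5p", "UGAGGUAGUAGGUUGUAUAGU")


@pytest.fixture
def small_registry(let7) -> Registry:
    return Registry([
        let7,
        MatureMiRNA("dme-miR-8-3p", "UAAUACUGUCAGGUAAAGAUGUC"),
        MatureMiRNA("dme-miR-2a-3p", "UAUCACAGCCAGCUUUGAUGAGC"),
        # shares the let-7 extended seed (positions 2-8): family member
        MatureMiRNA("dme-let-7-alt", "UGAGGUAGUUUUUUGUAUAGUA"),
    ])


@pytest.fixture
def mature_fasta(tmp_path):
    """Write a mature-FASTA file from (header, sequence) pairs."""

    def _write(records, name="mature.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write
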