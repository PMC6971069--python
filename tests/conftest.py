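import pytest

from cbcscope.structure import is_complementary


def enumerate_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Exhaustive-enumeration oracle: max pairs over all nested structures.

    Generates every nested pair set explicitly (no DP recurrence), so it is an
    independent check of the dynamic-programming fold for short sequences.
    """

    def structures(i: int, j: int):
        if i >= j:
            yield frozenset()
            return
        yield from structures(i + 1, j)
        for k in range(i + 1, j + 1):
            if k - i > min_loop and is_complementary(seq[i - 1], seq[k - 1]) is True:
                for left in structures(i + 1, k - 1):
                    for right in structures(k + 1, j):
                        yield left | right | {(i, k)}

    return max((len(s) for s in structures(1, len(seq))), default=0)


@pytest.fixture
def brute_force_fold():
    return enumerate_max_pairs


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(name, records):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
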