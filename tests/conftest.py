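import numpy as np
import pytest

from genecontent.trees import Tree


@pytest.fixture
def balanced4() -> Tree:
    """((A,B),(C,D)) — the smallest tree with two cherries."""
    return Tree.from_newick("((A,B),(C,D));")


@pytest.fixture
def caterpillar5() -> Tree:
    return Tree.from_newick("((((A,B),C),D),E);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230622)


def all_tree_shapes(n_tips: int) -> list[str]:
    """Newick strings for every rooted binary tree shape with n_tips leaves.

    Shapes (not labelled trees): leaves get fixed labels in left-to-right
    order, so Wedderburn–Etherington counts apply (1, 1, 1, 2, 3, 6 for
    n = 1..6).
    """

    def shapes(n: int) -> list[str]:
        if n == 1:
            return ["*"]
        out = []
        seen = set()
        for n1 in range(1, n // 2 + 1):
            for left in shapes(n1):
                for right in shapes(n - n1):
                    s = f"({left},{right})"
                    canon = _canonical(s)
                    if canon not in seen:
                        seen.add(canon)
                        out.append(s)
        return out

    def _canonical(s: str) -> str:
        # canonical form by recursive sorted children
        def parse(i):
            if s[i] == "(":
                i += 1
                a, i = parse(i)
                assert s[i] == ","
                b, i = parse(i + 1)
                assert s[i] == ")"
                return tuple(sorted((a, b), key=repr)), i + 1
            return "*", i + 1

        tree, _ = parse(0)
        return repr(tree)

    labelled = []
    for shape in shapes(n_tips):
        counter = iter("ABCDEFGH")
        labelled.append(
            "".join(next(counter) if ch == "*" else ch for ch in shape) + ";"
        )
    return labelled
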