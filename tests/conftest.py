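import numpy as np
import pandas as pd

from phenoanchor import CountMatrix


def toy_count_matrix(values: np.ndarray, n_groups: int = 2) -> CountMatrix:
    """Wrap a genes x samples array as a CountMatrix with a simple design."""
    genes = [f"g{i}" for i in range(values.shape[0])]
    n = values.shape[1]
    per = n // n_groups
    cols, meta = [], []
    for j in range(n):
        grp = min(j // per, n_groups - 1)
        conc = 0.0 if grp == 0 else float(grp)
        name = f"s{j}"
        cols.append(name)
        meta.append(
            dict(sample=name, chemical="control" if conc == 0 else "X",
                 concentration_uM=conc, timepoint_hpf=48.0, replicate=j % per + 1)
        )
    return CountMatrix(
        pd.DataFrame(values, index=genes, columns=cols),
        pd.DataFrame(meta).set_index("sample"),
    )
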