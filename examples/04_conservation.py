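"""Sequence conservation versus conformational conservation.

Builds an alignment whose column variability tracks a per-residue
flexibility profile (flexible residues mutate more), with 20 planted
columns that are fully conserved despite high flexibility.  Computes SCS
and 3DCS, correlates them, and shows that flagging and excluding the
planted anticorrelated residues raises the correlation.
"""

import numpy as np
import pandas as pd

from saxsemble import (
    build_conservation_table,
    correlate_and_flag,
    generate_coupled_msa,
    sequence_conservation_score,
)

rng = np.random.default_rng(11)
rmsf = rng.uniform(0.5, 25.0, size=400)          # per-residue flexibility, Å
planted = np.argsort(rmsf)[-20:]                 # most flexible residues

msa, _ = generate_coupled_msa(rmsf, n_sequences=114, coupling=-1.0, seed=11,
                              planted_anticorrelated=planted)
mapping = {j: j + 1 for j in range(400)}
scs = sequence_conservation_score(msa, mapping)
table = build_conservation_table(scs, pd.Series(rmsf, index=scs.index))
stats = correlate_and_flag(table)

print(f"r(SCS, 3DCS) overall          : {stats['r_overall']:.2f}")
print(f"planted outliers flagged      : "
      f"{len(set(planted + 1) & set(stats['flagged_high_scs_low_3dcs']))} / 20")
print(f"r after excluding flagged     : {stats['r_excluding_flagged']:.2f}")
print("(conserved-but-mobile residues depress the raw correlation; once")
print(" flagged and excluded, conservation tracks rigidity much more tightly)")
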