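"""Signal detection on a synthetic quarter: from raw tables to flags.

Assembles the dataset (deduplication, synonym matching, suspect-role
filtering) and screens every (drug group, preferred term) pair with the
ROR, PRR and BCPNN criteria.
"""

import pandas as pd

from pvsignal import (SynonymDictionary, assemble_dataset, detect_signals,
                      generate, toy_config)

bundle, truth = generate(toy_config(seed=42))
dictionary = SynonymDictionary({"CDOX": "CDOX", "DOXORUBICIN": "CDOX",
                                "DOXIL": "DOXIL", "CAELYX": "DOXIL",
                                "MYOCET": "MYOCET"})
dataset = assemble_dataset(bundle, dictionary)
print(f"{dataset.n_reports} deduplicated reports; "
      f"drug groups: {dataset.drug_groups}")

signals = detect_signals(dataset)
flagged = signals[signals[["flag_ror", "flag_prr", "flag_bcpnn"]].any(axis=1)]
cols = ["pt", "drug_group", "a", "ror", "ror_ci_low", "prr", "chi2", "ic025"]
with pd.option_context("display.width", 120):
    print(flagged[cols].round(2).to_string(index=False))
print()
print("Planted pairs (CDOX/febrile neutropenia, DOXIL/hand-foot syndrome,")
print("MYOCET/cardiotoxicity) surface with elevated RORs; at 200 reports")
print("only the stronger ones clear every threshold.")
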