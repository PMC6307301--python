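"""Screen genomes for biotin/cobalamin prototrophy and nominate syntrophies.

A genome with the complete core biosynthesis gene set is a prototroph; an
incomplete genome with a salvage transporter (e.g. the BioYM ECF-type
biotin transporter) can scavenge the cofactor instead.  Prototroph groups
positively associated with auxotroph groups in the co-occurrence network
are candidate cofactor donors - a mechanism by which enriched organisms
could help resuscitate auxotrophic neighbours.
"""

import pandas as pd

from enrichseq import biotin_pathway, cobalamin_pathway, screen_genomes
from enrichseq.pathways import syntrophy_candidates

core = biotin_pathway().core_synthesis_genes
presence = pd.DataFrame(
    {
        "family": ["Vibrionaceae", "Marinilabiliaceae", "Lentimicrobiaceae"],
        **{g: [1, 0, 0] for g in core},
        "bioA": [1, 1, 0],   # the auxotroph keeps a pathway fragment
        "bioY": [0, 1, 0],
        "bioM": [0, 1, 0],
    },
    index=["gen_vibrio", "gen_marinilab", "gen_lenti"],
)

trophy = screen_genomes(presence, [biotin_pathway()])
print(trophy[["genome_id", "group", "completeness", "trophy"]].to_string(index=False))

associations = pd.DataFrame(
    [
        {"group_a": "Marinilabiliaceae", "group_b": "Vibrionaceae",
         "n_positive": 3, "n_negative": 0, "net_sign": "positive"},
        {"group_a": "Lentimicrobiaceae", "group_b": "Marinilabiliaceae",
         "n_positive": 0, "n_negative": 2, "net_sign": "negative"},
    ]
)
candidates = syntrophy_candidates(trophy, associations)
print("\nsyntrophy candidates:")
print(candidates.to_string(index=False))
# Only the positively associated prototroph->auxotroph direction is
# nominated: the negative association never yields a candidate.
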