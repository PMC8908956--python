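# Participant roster for the figurine-inspired creative-works study.
# One row per artist; members of the musical group SLT carry SLT in the
# `group` column and are counted through the group, not separately.
# experience_years is the stated lower bound ("> N years" -> N).
code	medium	age	nationality	experience_years	group	provided_description
SLT	Music (group)	-	-	-	-	yes
AS	Music - Percussion	33	USA	15	SLT	-
LN	Music - Vocals	36	Canada	20	SLT	-
ND	Music - Cello / Computer	27	Persia/Russia	10	SLT	-
SW	Written word (Novelist)	71	Australia	30	-	yes
WC	Music	67	Australia	30	-	yes
MG	Music	38	USA	20	-	-
LH	Written word (Poetry)	78	Australia	30	-	-
SD	Visual Art	64	Canada/USA	30	-	-
SB	Written word (Novelist and Playwright)	67	USA	30	-	-
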