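# Column mapping template for the Experiment 1/2 style deposit layout
# (4-point accuracy ratings, 1-7 conservatism, no PANAS).
#
# The deposited tables' exact column names are not standardized; edit the
# right-hand side to match the headers of the file you downloaded.  Keys on
# the left are the canonical field names the loader expects.
participant_id: subject
item_id: item
raw_rating: accuracy_rating        # 1-4; binarized at the 2/3 midpoint
reaction_time: rt_accuracy
crt: crt_score                     # mean fraction of correct CRT answers
conservatism: conservatism         # 1-7 scale
education: education
truth: veracity                    # real/fake (aliases: true/false, 1/0)
part_rep: partisanship_rep         # pretest aggregates, 1-5 scale
part_dem: partisanship_dem
fam_rep: familiarity_rep           # pretest aggregates, 1-3 scale
fam_dem: familiarity_dem
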