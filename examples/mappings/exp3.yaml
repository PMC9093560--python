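# Column mapping template for the Experiment 3 style deposit layout
# (binary accuracy responses, 1-5 conservatism, PANAS and the extra
# pretest measures present).  Edit right-hand names to match your file.
participant_id: subject
item_id: item
response: accuracy_response        # binary yes/no (aliases: accept/reject, 1/0)
reaction_time: rt_accuracy
crt: crt_score
conservatism: conservatism         # 1-5 scale
education: education
panas_p: panas_pos
panas_n: panas_neg
truth: veracity
part_rep: partisanship_rep
part_dem: partisanship_dem
fam_rep: familiarity_rep
fam_dem: familiarity_dem
importance_rep: importance_rep
importance_dem: importance_dem
worrying_rep: worrying_rep
worrying_dem: worrying_dem
exciting_rep: exciting_rep
exciting_dem: exciting_dem
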