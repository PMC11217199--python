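scenario,step_id,step_name,mode,consumables,staff,equipment,reimbursement
reference,1,Pretest Evaluation,reimbursement,,,,104.53
reference,2,Peripheral Blood Collection,microcost,6.67,4.76,0.11,
reference,3,DNA Extraction,microcost,16.35,4.25,2.80,
reference,4,Library,microcost,139.22,0.11,2.86,
reference,5,NGS,microcost,118.30,0.11,3.93,
reference,6,Analysis,microcost,0.17,75.56,0.55,
reference,7,Sanger Sequencing,microcost,42.96,8.49,26.12,
reference,8,Posttest Evaluation,reimbursement,,,,67.72
reference,operation,Operation,microcost,4.70,21.83,0.00,
alternative,1,Pretest Evaluation,reimbursement,,,,104.53
alternative,2,Peripheral Blood Collection,microcost,6.67,1.23,0.01,
alternative,3,DNA Extraction,microcost,16.35,0.87,0.08,
alternative,4,Library,microcost,139.22,0.11,2.86,
alternative,5,NGS,microcost,118.30,0.11,3.93,
alternative,6,Analysis,microcost,0.00,15.76,0.08,
alternative,7,Sanger Sequencing,microcost,42.96,0.22,0.69,
alternative,8,Posttest Evaluation,reimbursement,,,,67.72
alternative,operation,Operation,microcost,1.77,0.56,0.00,
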