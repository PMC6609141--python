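service_id,label,sector,unit_cost
school_nurse,School nurse,education,50.00
school_counsellor,School counsellor/guidance teacher,education,35.02
intervention_teacher,Intervention teacher,education,25.89
educational_psychologist,Educational psychologist,education,41.00
education_welfare_officer,Education welfare officer/home school liaison officer,education,27.00
gp_surgery_visit,GP surgery visit,health,46.00
gp_out_of_hours,GP out of hours,health,115.00
nurse_other,Nurse (other than school nurse),health,13.70
hospital_appointment,Hospital appointment,health,109.00
accident_emergency,Accident and emergency,health,233.00
overnight_hospital_stay,Overnight hospital stay,health,658.33
psychologist,Psychologist,health,50.00
counsellor_other,Counsellor (other than at school),health,50.00
social_worker,Social worker,health,79.00
telephone_helpline,Telephone help-line,health,3.99
youth_justice,Youth justice service,criminal_justice,84.00
police_service,Police service,criminal_justice,325.00
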