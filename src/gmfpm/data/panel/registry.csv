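variable,kind,domain,value_set,elements
Drooling,derived,Motor Performance,concern_summary,Drooling|Drooling oral motor function
Sitting Balance,unique,Motor Performance,sitting_balance,Sitting balance
Knee Tone,derived,Motor Performance,mas,Knee extensor tone|Knee flexor tone
Ankle Tone,derived,Motor Performance,mas,Ankle dorsiflexor tone|Plantar flexor tone
Elbow Tone,derived,Motor Performance,mas,Elbow Extensor Tone|Elbow flexor tone
Neck Strength,unique,Motor Performance,neck_strength,Neck Strength
Cognitive Concerns,derived,Neurologic Function,concern_summary,Cognitive deficits|Speech deficit
Communication Concerns,derived,Neurologic Function,concern_summary,Language delay|Language impairment|Speech delay|Speech impairment
Assistive Devices Used,derived,Device Use,assistive_summary,Walker|Cane|Crutches
Mobility Device Used,derived,Device Use,mobility_summary,Wheelchair independently|Manual wheelchair|Unable to propel own wheelchair|Power wheelchair
Ambulation Device Used,derived,Device Use,yes_no,"Gait trainer|Swivel walker|Walker pickup|Walker reverse|Walker wheeled|Crutches forearm|Cane, quad|Cane, single point|Cane, tripod|Crutches axillary|Stander|None"
Stair Railings,unique,Device Use,stair_railings,Stair Railings
Current Home Treatments,derived,Activity Performance,treatments_summary,Respiratory support|Trach care|Tube feeding|Urinary catheterization
Fine Motor Concerns,derived,Activity Performance,fine_motor_summary,Dressing|Feeding|Grooming|Bathing
Toileting Habits,derived,Activity Performance,yes_no,Toilet trained|Diaper at night
Feeding Ability,derived,Activity Performance,yes_no,Feeds self|Complete independence|Modified independence|Supervision|Minimal assistance|Moderate Assistance|Maximal assistance|No oral feedings|Total assistance
Gross Motor Concerns,derived,Mobility Performance,concern_summary,Ambulatory with assistance|Assistive devices needed|Household ambulation|Tires easily|Trips/falls frequently|Unable to sit independently|Non-ambulatory
Ambulation Level,unique,Mobility Performance,ambulation_level,Ambulation Level
Stairs Assistance,unique,Mobility Performance,stairs_assistance,Stairs Assistance
Primary Mobility,unique,Mobility Performance,primary_mobility,Primary Mobility
General Lower Extremity Muscle Tone,unique,Motor Performance,yes_no,General lower extremity muscle tone
Pain with Movement,unique,Motor Performance,yes_no,Pain with movement
Vision Concerns,unique,Neurologic Function,yes_no,Vision concerns
Hearing Concerns,unique,Neurologic Function,yes_no,Hearing concerns
Seizure History,unique,Neurologic Function,yes_no,Seizure history
Orthotics Worn,derived,Device Use,yes_no,AFO worn|KAFO worn|TLSO worn
Endurance Concerns,derived,Mobility Performance,yes_no,Tires with walking|Tires with stairs
School Mobility Concerns,derived,Mobility Performance,yes_no,Needs aide at school|Needs transport assistance
No Fine Motor Concerns,unique,Activity Performance,yes_no,No fine motor concerns
No Gross Motor Concerns,unique,Mobility Performance,yes_no,No gross motor concerns
No Home Treatments,unique,Activity Performance,yes_no,No home treatments
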