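panelist_id,variable,rating
EXP1,Drooling,4
EXP1,Sitting Balance,3
EXP1,Knee Tone,4
EXP1,Ankle Tone,4
EXP1,Elbow Tone,2
EXP1,Neck Strength,3
EXP1,Cognitive Concerns,3
EXP1,Communication Concerns,4
EXP1,Assistive Devices Used,5
EXP1,Mobility Device Used,5
EXP1,Ambulation Device Used,4
EXP1,Stair Railings,2
EXP1,Current Home Treatments,4
EXP1,Fine Motor Concerns,3
EXP1,Toileting Habits,4
EXP1,Feeding Ability,3
EXP1,Gross Motor Concerns,5
EXP1,Ambulation Level,5
EXP1,Stairs Assistance,4
EXP1,Primary Mobility,5
EXP1,General Lower Extremity Muscle Tone,3
EXP1,Pain with Movement,1
EXP1,Vision Concerns,2
EXP1,Hearing Concerns,1
EXP1,Seizure History,2
EXP1,Orthotics Worn,1
EXP1,Endurance Concerns,2
EXP1,School Mobility Concerns,1
EXP1,No Fine Motor Concerns,4
EXP1,No Gross Motor Concerns,3
EXP1,No Home Treatments,5
EXP2,Drooling,3
EXP2,Sitting Balance,4
EXP2,Knee Tone,4
EXP2,Ankle Tone,3
EXP2,Elbow Tone,2
EXP2,Neck Strength,3
EXP2,Cognitive Concerns,4
EXP2,Communication Concerns,3
EXP2,Assistive Devices Used,4
EXP2,Mobility Device Used,5
EXP2,Ambulation Device Used,4
EXP2,Stair Railings,2
EXP2,Current Home Treatments,4
EXP2,Fine Motor Concerns,4
EXP2,Toileting Habits,3
EXP2,Feeding Ability,3
EXP2,Gross Motor Concerns,4
EXP2,Ambulation Level,5
EXP2,Stairs Assistance,4
EXP2,Primary Mobility,4
EXP2,General Lower Extremity Muscle Tone,3
EXP2,Pain with Movement,2
EXP2,Vision Concerns,2
EXP2,Hearing Concerns,1
EXP2,Seizure History,1
EXP2,Orthotics Worn,2
EXP2,Endurance Concerns,2
EXP2,School Mobility Concerns,1
EXP2,No Fine Motor Concerns,3
EXP2,No Gross Motor Concerns,4
EXP2,No Home Treatments,4
EXP3,Drooling,4
EXP3,Sitting Balance,3
EXP3,Knee Tone,3
EXP3,Ankle Tone,4
EXP3,Elbow Tone,declined
EXP3,Neck Strength,4
EXP3,Cognitive Concerns,3
EXP3,Communication Concerns,3
EXP3,Assistive Devices Used,4
EXP3,Mobility Device Used,4
EXP3,Ambulation Device Used,5
EXP3,Stair Railings,3
EXP3,Current Home Treatments,4
EXP3,Fine Motor Concerns,4
EXP3,Toileting Habits,3
EXP3,Feeding Ability,4
EXP3,Gross Motor Concerns,5
EXP3,Ambulation Level,5
EXP3,Stairs Assistance,3
EXP3,Primary Mobility,5
EXP3,General Lower Extremity Muscle Tone,4
EXP3,Pain with Movement,2
EXP3,Vision Concerns,2
EXP3,Hearing Concerns,2
EXP3,Seizure History,2
EXP3,Orthotics Worn,2
EXP3,Endurance Concerns,1
EXP3,School Mobility Concerns,1
EXP3,No Fine Motor Concerns,3
EXP3,No Gross Motor Concerns,3
EXP3,No Home Treatments,3
EXP4,Drooling,3
EXP4,Sitting Balance,4
EXP4,Knee Tone,5
EXP4,Ankle Tone,4
EXP4,Elbow Tone,3
EXP4,Neck Strength,2
EXP4,Cognitive Concerns,3
EXP4,Communication Concerns,2
EXP4,Assistive Devices Used,5
EXP4,Mobility Device Used,4
EXP4,Ambulation Device Used,3
EXP4,Stair Railings,4
EXP4,Current Home Treatments,3
EXP4,Fine Motor Concerns,4
EXP4,Toileting Habits,4
EXP4,Feeding Ability,5
EXP4,Gross Motor Concerns,4
EXP4,Ambulation Level,4
EXP4,Stairs Assistance,4
EXP4,Primary Mobility,5
EXP4,General Lower Extremity Muscle Tone,3
EXP4,Pain with Movement,1
EXP4,Vision Concerns,declined
EXP4,Hearing Concerns,3
EXP4,Seizure History,2
EXP4,Orthotics Worn,3
EXP4,Endurance Concerns,1
EXP4,School Mobility Concerns,2
EXP4,No Fine Motor Concerns,4
EXP4,No Gross Motor Concerns,2
EXP4,No Home Treatments,3
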