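tray_id,microhabitat,zone,set_id,n_exposed,n_surviving,censored
T001,OPEN,A,SA1,10,,true
T002,OPEN,A,SA2,10,1,false
T003,OPEN,A,SA3,10,0,false
T004,OPEN,A,SA4,10,2,false
T005,OPEN,A,SA5,10,3,false
T006,OPEN,A,SA6,10,0,false
T007,OPEN,A,SA7,10,0,false
T008,OPEN,A,SA8,10,0,false
T009,OPEN,A,SA9,10,0,false
T010,OPEN,A,SA10,10,1,false
T011,EPHEDRA,A,SA1,10,1,false
T012,EPHEDRA,A,SA2,10,0,false
T013,EPHEDRA,A,SA3,10,2,false
T014,EPHEDRA,A,SA4,10,1,false
T015,EPHEDRA,A,SA5,10,0,false
T016,EPHEDRA,A,SA6,10,0,false
T017,EPHEDRA,A,SA7,10,1,false
T018,EPHEDRA,A,SA8,10,0,false
T019,EPHEDRA,A,SA9,10,0,false
T020,EPHEDRA,A,SA10,10,0,false
T021,PISTACIA,A,SA1,10,3,false
T022,PISTACIA,A,SA2,10,2,false
T023,PISTACIA,A,SA3,10,1,false
T024,PISTACIA,A,SA4,10,1,false
T025,PISTACIA,A,SA5,10,0,false
T026,PISTACIA,A,SA6,10,1,false
T027,PISTACIA,A,SA7,10,0,false
T028,PISTACIA,A,SA8,10,0,false
T029,PISTACIA,A,SA9,10,1,false
T030,PISTACIA,A,SA10,10,1,false
T031,OPEN,B,SB1,10,,true
T032,OPEN,B,SB2,10,,true
T033,OPEN,B,SB3,10,,true
T034,OPEN,B,SB4,10,,true
T035,OPEN,B,SB5,10,0,false
T036,OPEN,B,SB6,10,1,false
T037,OPEN,B,SB7,10,0,false
T038,OPEN,B,SB8,10,1,false
T039,OPEN,B,SB9,10,0,false
T040,OPEN,B,SB10,10,1,false
T041,EPHEDRA,B,SB1,10,,true
T042,EPHEDRA,B,SB2,10,,true
T043,EPHEDRA,B,SB3,10,0,false
T044,EPHEDRA,B,SB4,10,0,false
T045,EPHEDRA,B,SB5,10,0,false
T046,EPHEDRA,B,SB6,10,0,false
T047,EPHEDRA,B,SB7,10,2,false
T048,EPHEDRA,B,SB8,10,1,false
T049,EPHEDRA,B,SB9,10,0,false
T050,EPHEDRA,B,SB10,10,0,false
T051,PISTACIA,B,SB1,10,0,false
T052,PISTACIA,B,SB2,10,2,false
T053,PISTACIA,B,SB3,10,0,false
T054,PISTACIA,B,SB4,10,2,false
T055,PISTACIA,B,SB5,10,0,false
T056,PISTACIA,B,SB6,10,2,false
T057,PISTACIA,B,SB7,10,4,false
T058,PISTACIA,B,SB8,10,3,false
T059,PISTACIA,B,SB9,10,1,false
T060,PISTACIA,B,SB10,10,1,false
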