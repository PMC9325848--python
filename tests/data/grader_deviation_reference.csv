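grader,role,dev0,dev1,dev2,dev3,dev4
Specialist 1,specialist,75.56,22.22,1.11,0,0
Specialist 2,specialist,73.33,26.67,0,0,0
Specialist 3,specialist,42.22,48.89,4.44,0,0
Specialist 4,specialist,54.44,32.22,4.44,0,1.11
Specialist 5,specialist,70.00,30.00,0,0,0
Specialist 6,specialist,71.11,28.89,0,0,0
Specialist 7,specialist,50.00,37.78,4.44,1.11,0
Specialist 8,specialist,67.78,27.78,2.22,0,0
Specialist 9,specialist,72.22,23.33,2.22,0,0
Resident 1,resident,64.44,26.67,4.44,0,0
Resident 2,resident,62.22,33.33,2.22,0,0
Resident 3,resident,58.89,34.44,3.33,0,0
Resident 4,resident,71.11,26.67,1.11,0,0
Resident 5,resident,61.11,34.44,2.22,0,0
Resident 6,resident,67.78,30.00,1.11,0,0
Resident 7,resident,66.67,28.89,2.22,0,0
Resident 8,resident,73.33,26.67,0,0,0
Resident 9,resident,25.56,46.67,8.89,3.33,0
Resident 10,resident,57.78,35.56,3.33,0,0
Resident 11,resident,45.56,40.00,5.56,1.11,0
Student 1,student,25.56,54.44,6.67,2.22,0
Student 2,student,73.33,24.44,1.11,0,0
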