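Task-operation showcase: the three kinds of task operation (uniform,
parameterised, residue-level), each feeding a differently restricted
packer.  This fragment is wrapped in a ROSETTASCRIPTS tag with an empty
PROTOCOLS section so it loads as a complete script.
<ROSETTASCRIPTS>
	<TASKOPERATIONS>
		<InitializeFromCommandline name = ifcm/> to make the Packer aware of command-line options
		<RestrictToRepacking name = no_mutations/> only repack; do not design
		<ReadResfile name = rrf filename = myresfile/> resfiles are external files that describe which residues are allowed to pack
		<OperateOnCertainResidues name = fix20to24>
			<PreventRepackingRLT/> do not change residues
			<ResidueIndexIs indices = 20,21,22,23,24/>
		</OperateOnCertainResidues>
		<OperateOnCertainResidues name = keepNonpolars>
			<RestrictToRepackingRLT/> only repack; do not design
			<ResidueLacksProperty property = POLAR/> operate on polar residues
		</OperateOnCertainResidues>
	</TASKOPERATIONS>
	<MOVERS>
		<PackRotamersMover name = packer scorefxn = score12 task_operations = ifcm,no_mutations/> score12 is the default all-atom energy function; PackRotamersMover invokes the Packer to design or repack sidechains
		<PackRotamersMover name = resfilepacker scorefxn = score12 task_operations = ifcm,rrf/>
		<PackRotamersMover name = anotherpacker scorefxn = score12 task_operations = ifcm,fix20to24,keepNonpolars/>
	</MOVERS>
	<PROTOCOLS>
	</PROTOCOLS>
</ROSETTASCRIPTS>
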